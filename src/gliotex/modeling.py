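"""Model selection, training, tuning and evaluation for glioma-grade classification.

Protocol: stratified ten-fold cross-validation compares seven standard
classifiers (k-NN, linear discriminant analysis, Gaussian naive Bayes,
decision tree, SVM, random forest, logistic regression) by mean fold
accuracy; the winner — a random forest in the reference protocol — is
trained at library defaults (100 trees, Gini, bootstrap) as the base model,
then tuned by grid or randomized CV search over n_estimators, max_depth,
min_samples_split, min_samples_leaf, max_features and bootstrap. The search
loop is explicit so ties resolve toward the simpler model (fewer trees,
then shallower depth). Evaluation reports overall accuracy, per-class
precision/recall/F1, the 3x3 confusion matrix and one-vs-rest ROC AUCs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import CLASSES
from .pipeline import FeatureTable

__all__ = [
    "ALGORITHM_NAMES",
    "CvReport",
    "RfHyperParams",
    "ModelReport",
    "PAPER_TUNED",
    "crossvalidate_algorithms",
    "train_base_model",
    "tune_hyperparameters",
    "evaluate_model",
]

ALGORITHM_NAMES: tuple[str, ...] = (
    "k-nearest neighbors",
    "linear discriminant analysis",
    "gaussian naive bayes",
    "decision tree",
    "support vector machine",
    "random forest",
    "logistic regression",
)


def _algorithms(seed: int) -> dict[str, object]:
    return {
        "k-nearest neighbors": KNeighborsClassifier(),
        "linear discriminant analysis": LinearDiscriminantAnalysis(),
        "gaussian naive bayes": GaussianNB(),
        "decision tree": DecisionTreeClassifier(random_state=seed),
        "support vector machine": SVC(random_state=seed),
        "random forest": RandomForestClassifier(random_state=seed),
        "logistic regression": LogisticRegression(max_iter=2000, random_state=seed),
    }


@dataclass
class CvReport:
    k: int
    mean_accuracy: dict[str, float]
    sd_accuracy: dict[str, float]

    @property
    def winner(self) -> str:
        # ties resolve by the fixed algorithm order, so the winner is
        # invariant to dict insertion games
        best = max(self.mean_accuracy.values())
        for name in ALGORITHM_NAMES:
            if self.mean_accuracy[name] == best:
                return name
        raise RuntimeError("unreachable")


@dataclass
class RfHyperParams:
    n_estimators: int = 100
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    max_features: str | int | float = "sqrt"  # the legacy "auto" = sqrt(n_features)
    bootstrap: bool = True

    def build(self, seed: int = 42) -> RandomForestClassifier:
        return RandomForestClassifier(random_state=seed, **asdict(self))


#: Reported optimum of the reference protocol, shipped as a named preset.
PAPER_TUNED = RfHyperParams(
    n_estimators=108,
    max_depth=50,
    min_samples_split=2,
    min_samples_leaf=1,
    max_features="sqrt",
    bootstrap=False,
)


@dataclass
class ModelReport:
    """Full evaluation of one fitted classifier on a held-out set."""

    accuracy: float              # fraction in [0, 1]
    error: float                 # 1 - accuracy
    precision: dict[str, float]  # per class, full precision
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    confusion: np.ndarray        # rows = true class code, cols = predicted
    ovr_auc: dict[str, float] = field(default_factory=dict)
    undefined_classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        total = self.confusion.sum()
        if total and abs(self.accuracy - np.trace(self.confusion) / total) > 1e-12:
            raise ValueError("accuracy inconsistent with confusion matrix trace")

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.accuracy

    @property
    def error_percent(self) -> float:
        return 100.0 * self.error

    def rounded(self, decimals: int = 2) -> dict:
        """Report-card rendering (per-class metrics at fixed decimals)."""
        rnd = lambda d: {k: round(v, decimals) for k, v in d.items()}
        return {
            "accuracy_percent": round(self.accuracy_percent, 2),
            "precision": rnd(self.precision),
            "recall": rnd(self.recall),
            "f1": rnd(self.f1),
            "support": self.support,
        }

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "error": self.error,
            "accuracy_percent": self.accuracy_percent,
            "error_percent": self.error_percent,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
            "confusion": self.confusion.tolist(),
            "ovr_auc": self.ovr_auc,
            "undefined_classes": self.undefined_classes,
        }


def report_from_confusion(confusion: np.ndarray) -> ModelReport:
    """Rebuild the metric report implied by a 3x3 confusion matrix alone.

    Rows are true classes (code order GBM/HGG/LGG), columns predictions.
    Useful for checking printed confusion counts against printed metrics.
    """
    C = np.asarray(confusion, dtype=int)
    total = C.sum()
    accuracy = np.trace(C) / total
    precision, recall, f1, support = {}, {}, {}, {}
    for k, cls in enumerate(CLASSES):
        col = C[:, k].sum()
        row = C[k, :].sum()
        precision[cls] = C[k, k] / col if col else 0.0
        recall[cls] = C[k, k] / row if row else 0.0
        denom = precision[cls] + recall[cls]
        f1[cls] = 2 * precision[cls] * recall[cls] / denom if denom else 0.0
        support[cls] = int(row)
    return ModelReport(
        accuracy=float(accuracy),
        error=float(1 - accuracy),
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        confusion=C,
    )


def crossvalidate_algorithms(
    train: FeatureTable, k: int = 10, seed: int = 42
) -> CvReport:
    """Score the seven candidate algorithms by stratified k-fold CV accuracy."""
    y = train.labels
    min_class = min(train.class_counts().values())
    if min_class < k:
        k = max(2, min_class)
        import warnings

        warnings.warn(f"smallest class has {min_class} rows; reducing folds to {k}")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X = train.features.to_numpy(dtype=float)
    means, sds = {}, {}
    for name, est in _algorithms(seed).items():
        scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
        means[name] = float(scores.mean())
        sds[name] = float(scores.std())
    return CvReport(k=k, mean_accuracy=means, sd_accuracy=sds)


def train_base_model(
    train: FeatureTable, test: FeatureTable | None = None, seed: int = 42
) -> tuple[RandomForestClassifier, ModelReport | None]:
    """Fit the base random forest (library defaults, fixed random state)."""
    model = RandomForestClassifier(random_state=seed)
    model.fit(train.features.to_numpy(dtype=float), train.labels)
    report = evaluate_model(model, test) if test is not None else None
    return model, report


def default_search_space() -> dict[str, list]:
    """The tuning ranges of the reference protocol.

    n_estimators 100..1000 (grid: step 400), max_depth 10..110 in 11 steps,
    min_samples_split {2, 5, 10}, min_samples_leaf {1, 2, 4},
    max_features sqrt ("auto"), bootstrap {True, False}.
    """
    return {
        "n_estimators": list(range(100, 1001, 400)),
        "max_depth": [int(d) for d in np.linspace(10, 110, 11)],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 2, 4],
        "max_features": ["sqrt"],
        "bootstrap": [True, False],
    }


def _simplicity_key(p: dict) -> tuple:
    depth = p["max_depth"] if p["max_depth"] is not None else np.inf
    return (p["n_estimators"], depth)


def tune_hyperparameters(
    train: FeatureTable,
    grid_spec: dict[str, list] | None = None,
    method: str = "random",
    k: int = 10,
    seed: int = 42,
    n_iter: int = 100,
) -> tuple[RfHyperParams, float]:
    """CV search over random-forest hyperparameters; returns (best, CV accuracy).

    ``grid`` enumerates the full cartesian grid; ``random`` draws ``n_iter``
    combinations treating n_estimators and max_depth as integer ranges
    spanned by the grid. Ties in mean CV accuracy break toward the simpler
    model: fewer trees, then shallower depth.
    """
    space = grid_spec or default_search_space()
    if any(len(v) == 0 for v in space.values()):
        raise ValueError("empty hyperparameter grid")
    rng = np.random.default_rng(seed)
    keys = list(space)

    if method == "grid":
        candidates = [dict(zip(keys, combo)) for combo in itertools.product(*space.values())]
    elif method == "random":
        candidates = []
        for _ in range(n_iter):
            cand = {}
            for key, vals in space.items():
                ints = [v for v in vals if isinstance(v, (int, np.integer))]
                if key in ("n_estimators", "max_depth") and len(ints) == len(vals) > 1:
                    cand[key] = int(rng.integers(min(ints), max(ints) + 1))
                else:
                    cand[key] = vals[int(rng.integers(len(vals)))]
            candidates.append(cand)
    else:
        raise ValueError(f"unknown search method {method!r}")

    X = train.features.to_numpy(dtype=float)
    y = train.labels
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    base = RandomForestClassifier(random_state=seed)

    best_params, best_score = None, -np.inf
    for cand in candidates:
        est = clone(base).set_params(**cand)
        score = float(cross_val_score(est, X, y, cv=cv, scoring="accuracy").mean())
        if score > best_score or (
            score == best_score
            and best_params is not None
            and _simplicity_key(cand) < _simplicity_key(best_params)
        ):
            best_params, best_score = cand, score
    assert best_params is not None
    return RfHyperParams(**best_params), best_score


def evaluate_model(model, test: FeatureTable) -> ModelReport:
    """Evaluate a fitted classifier on a prepared held-out set."""
    X = test.features.to_numpy(dtype=float)
    y = test.labels
    pred = model.predict(X)
    codes = list(range(len(CLASSES)))
    C = confusion_matrix(y, pred, labels=codes)
    prec, rec, f1, supp = precision_recall_fscore_support(
        y, pred, labels=codes, zero_division=0
    )
    undefined = [CLASSES[c] for c in codes if (y == c).sum() == 0]

    ovr_auc: dict[str, float] = {}
    if hasattr(model, "predict_proba") and not undefined:
        proba = model.predict_proba(X)
        aucs = roc_auc_score(y, proba, multi_class="ovr", average=None, labels=codes)
        ovr_auc = {CLASSES[c]: float(a) for c, a in zip(codes, aucs)}

    acc = float(accuracy_score(y, pred))
    return ModelReport(
        accuracy=acc,
        error=1.0 - acc,
        precision={CLASSES[c]: float(p) for c, p in zip(codes, prec)},
        recall={CLASSES[c]: float(r) for c, r in zip(codes, rec)},
        f1={CLASSES[c]: float(v) for c, v in zip(codes, f1)},
        support={CLASSES[c]: int(s) for c, s in zip(codes, supp)},
        confusion=C,
        ovr_auc=ovr_auc,
        undefined_classes=undefined,
    )
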