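"""Feature-table preparation: SMOTE balancing, splitting, scaling, ANOVA selection.

The central object is the :class:`FeatureTable` — per-slice feature rows
plus integer class labels (0=GBM, 1=HGG, 2=LGG). Preparation runs

    SMOTE balance -> stratified 70:30 split -> standardize (fit on train)
    -> ANOVA F-test -> drop the lowest-scoring features

SMOTE is implemented directly from its definition: a synthetic minority
point is ``x + u * (z - x)`` for a random minority example x, one of its k
nearest same-class neighbours z and u ~ Uniform(0, 1). The one-way ANOVA F
statistic is likewise computed from its between/within mean-square
definition (tests cross-check both against library routines).

Two protocol modes exist: ``paper`` balances the whole table before
splitting (faithful to the protocol this pipeline reproduces, but synthetic
neighbours leak across the split) and ``sound`` balances the training fold
only. Both are first-class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .cohort import CLASSES, CLASS_CODES

__all__ = [
    "FeatureTable",
    "SmoteConfig",
    "StandardizationParams",
    "AnovaReport",
    "smote_oversample",
    "split_train_test",
    "fit_standardizer",
    "apply_standardizer",
    "anova_f_scores",
    "select_features",
    "prepare",
]


@dataclass
class FeatureTable:
    """Numeric feature matrix with class labels and provenance."""

    features: pd.DataFrame
    labels: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")
        if len(self.labels) and not np.isin(self.labels, list(CLASS_CODES.values())).all():
            raise ValueError("labels must be class codes 0/1/2")
        self.features = self.features.reset_index(drop=True)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.labels == CLASS_CODES[c]).sum()) for c in CLASSES}

    def with_(self, features: pd.DataFrame | None = None,
              labels: np.ndarray | None = None,
              provenance: str | None = None) -> "FeatureTable":
        return FeatureTable(
            features=self.features if features is None else features,
            labels=self.labels if labels is None else labels,
            provenance=self.provenance if provenance is None else provenance,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "who_class") -> "FeatureTable":
        labels = df[label_column]
        if labels.dtype == object:
            labels = labels.map(CLASS_CODES)
        return cls(features=df.drop(columns=[label_column]), labels=labels.to_numpy())

    def to_dataframe(self, label_column: str = "who_class") -> pd.DataFrame:
        out = self.features.copy()
        out[label_column] = self.labels
        return out


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_per_class: int | str = "max-class"
    rng_seed: int = 42


@dataclass
class StandardizationParams:
    """Frozen per-feature scaling statistics, fitted on training rows only."""

    mode: str  # "zscore" | "minmax"
    feature_names: list[str]
    center: np.ndarray  # mean (zscore) or min (minmax)
    scale: np.ndarray   # sd (zscore) or max-min (minmax); 1.0 where degenerate
    constant_features: list[str] = field(default_factory=list)


@dataclass
class AnovaReport:
    f_scores: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)
    excluded_features: list[str] = field(default_factory=list)


def smote_oversample(table: FeatureTable, cfg: SmoteConfig | None = None) -> FeatureTable:
    """Balance class sizes by synthetic minority over-sampling.

    Every class below the target size is topped up with points interpolated
    between a random member and one of its k nearest same-class neighbours
    (Euclidean distance in raw feature space). Original rows are preserved
    verbatim and come first in the output.
    """
    cfg = cfg or SmoteConfig()
    if cfg.k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    rng = np.random.default_rng(cfg.rng_seed)

    counts = table.class_counts()
    if cfg.target_per_class == "max-class":
        target = max(counts.values())
    else:
        target = int(cfg.target_per_class)

    X = table.features.to_numpy(dtype=float)
    new_rows: list[np.ndarray] = []
    new_labels: list[int] = []
    for cls in CLASSES:
        code = CLASS_CODES[cls]
        need = target - counts[cls]
        if need <= 0:
            continue
        members = X[table.labels == code]
        if len(members) <= cfg.k_neighbors:
            raise ValueError(
                f"class {cls} has {len(members)} rows; needs > k_neighbors={cfg.k_neighbors}"
            )
        nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(members)
        # drop each point's self-match in column 0
        neigh_idx = nn.kneighbors(members, return_distance=False)[:, 1:]
        for _ in range(need):
            i = int(rng.integers(len(members)))
            z = members[neigh_idx[i][int(rng.integers(cfg.k_neighbors))]]
            u = rng.uniform()
            new_rows.append(members[i] + u * (z - members[i]))
            new_labels.append(code)

    if not new_rows:
        return table.with_(provenance="balanced")
    features = pd.DataFrame(
        np.vstack([X, np.array(new_rows)]), columns=table.feature_names
    )
    labels = np.concatenate([table.labels, np.array(new_labels, dtype=int)])
    return FeatureTable(features=features, labels=labels, provenance="balanced")


def split_train_test(
    table: FeatureTable, test_fraction: float = 0.30, seed: int = 42
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test partition of the feature rows.

    Per-class allocation follows the standard stratified splitter, so each
    class's test share is within one row of ``test_fraction`` and the two
    parts partition the input exactly.
    """
    if test_fraction == 0:
        return table, table.with_(
            features=table.features.iloc[0:0], labels=table.labels[:0]
        )
    counts = table.class_counts()
    if min(counts.values()) < 2:
        raise ValueError("every class needs at least 2 rows to split")
    idx_train, idx_test = train_test_split(
        np.arange(table.n_rows),
        test_size=test_fraction,
        random_state=seed,
        stratify=table.labels,
    )
    mk = lambda idx: table.with_(
        features=table.features.iloc[np.sort(idx)],
        labels=table.labels[np.sort(idx)],
    )
    return mk(idx_train), mk(idx_test)


def fit_standardizer(train: FeatureTable, mode: str = "zscore") -> StandardizationParams:
    """Fit per-feature scaling on the training rows only.

    ``zscore`` centres to zero mean / unit (population) variance; ``minmax``
    rescales to [0, 1] by the training min/max. Constant features are
    flagged and later emitted as all-zero instead of dividing by zero.
    """
    X = train.features.to_numpy(dtype=float)
    if mode == "zscore":
        scaler = StandardScaler().fit(X)
        center, scale = scaler.mean_, np.sqrt(scaler.var_)
    elif mode == "minmax":
        scaler = MinMaxScaler().fit(X)
        center, scale = scaler.data_min_, scaler.data_max_ - scaler.data_min_
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    constant = [n for n, s in zip(train.feature_names, scale) if s == 0]
    safe_scale = np.where(scale == 0, 1.0, scale)
    return StandardizationParams(
        mode=mode,
        feature_names=list(train.feature_names),
        center=np.array(center, copy=True),
        scale=safe_scale,
        constant_features=constant,
    )


def apply_standardizer(params: StandardizationParams, table: FeatureTable) -> FeatureTable:
    """Apply frozen scaling parameters; never re-fits."""
    if table.feature_names != params.feature_names:
        raise ValueError("feature names differ from those the standardizer was fitted on")
    X = table.features.to_numpy(dtype=float)
    Xs = (X - params.center) / params.scale
    for name in params.constant_features:
        Xs[:, params.feature_names.index(name)] = 0.0
    return table.with_(
        features=pd.DataFrame(Xs, columns=params.feature_names),
        provenance="standardized",
    )


def anova_f_scores(train: FeatureTable) -> AnovaReport:
    """One-way ANOVA F statistic of every feature against the class labels.

    F = between-group mean square / within-group mean square over the class
    groups, computed from the sums of squares directly. Degenerate cases are
    flagged: an overall-constant feature scores 0 (``constant``), a feature
    with zero within-class spread but distinct class means scores +inf
    (``perfect-separator``).
    """
    labels = train.labels
    codes = np.unique(labels)
    if len(codes) < 2:
        raise ValueError("ANOVA needs at least 2 classes")
    n = len(labels)
    if any((labels == c).sum() < 2 for c in codes):
        raise ValueError("every class needs at least 2 rows")

    scores: dict[str, float] = {}
    flags: dict[str, str] = {}
    for name in train.feature_names:
        x = train.features[name].to_numpy(dtype=float)
        grand = x.mean()
        ss_between = 0.0
        ss_within = 0.0
        for c in codes:
            g = x[labels == c]
            ss_between += len(g) * (g.mean() - grand) ** 2
            ss_within += ((g - g.mean()) ** 2).sum()
        ms_between = ss_between / (len(codes) - 1)
        ms_within = ss_within / (n - len(codes))
        if ms_within == 0.0:
            if ms_between == 0.0:
                scores[name] = 0.0
                flags[name] = "constant"
            else:
                scores[name] = float("inf")
                flags[name] = "perfect-separator"
        else:
            scores[name] = float(ms_between / ms_within)
    return AnovaReport(f_scores=scores, flags=flags)


def select_features(
    report: AnovaReport, table: FeatureTable, drop_count: int = 3
) -> tuple[FeatureTable, AnovaReport]:
    """Drop the ``drop_count`` lowest-F features (ties broken by column order)."""
    names = table.feature_names
    if drop_count >= len(names):
        raise ValueError("drop_count must be below the feature count")
    if drop_count:
        order = sorted(range(len(names)), key=lambda i: (report.f_scores[names[i]], i))
        dropped = [names[i] for i in order[:drop_count]]
    else:
        dropped = []
    report.excluded_features = dropped
    kept = [n for n in names if n not in dropped]
    return table.with_(features=table.features[kept], provenance="selected"), report


def prepare(
    table: FeatureTable,
    mode: str = "paper",
    scaler: str = "zscore",
    drop_count: int = 3,
    test_fraction: float = 0.30,
    split_seed: int = 42,
    smote_cfg: SmoteConfig | None = None,
) -> tuple[FeatureTable, FeatureTable, StandardizationParams, AnovaReport]:
    """Run the full preparation protocol; returns (train, test, scaler, anova).

    ``mode="paper"`` applies SMOTE to the whole table before splitting;
    ``mode="sound"`` splits first and balances only the training fold.
    """
    if mode == "paper":
        balanced = smote_oversample(table, smote_cfg)
        train, test = split_train_test(balanced, test_fraction, seed=split_seed)
    elif mode == "sound":
        train, test = split_train_test(table, test_fraction, seed=split_seed)
        train = smote_oversample(train, smote_cfg)
    else:
        raise ValueError(f"unknown protocol mode {mode!r}")

    params = fit_standardizer(train, mode=scaler)
    train_std = apply_standardizer(params, train)
    test_std = apply_standardizer(params, test)
    report = anova_f_scores(train_std)
    train_sel, report = select_features(report, train_std, drop_count)
    test_sel = test_std.with_(
        features=test_std.features[train_sel.feature_names], provenance="selected"
    )
    return train_sel, test_sel, params, report
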