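#!/usr/bin/env python
"""Train the base random forest, tune it, and report test-set performance.

Reads results/train.csv and results/test.csv (step 03). The base model is
a random forest at library defaults (100 trees, Gini, bootstrap); tuning
is a randomized CV search over n_estimators, max_depth, min_samples_split,
min_samples_leaf and bootstrap. Writes results/model_report.json,
results/confusion_tuned.csv and, if matplotlib is importable,
results/roc_tuned.png (one-vs-rest ROC curves).
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from gliotex import (
    CLASSES,
    FeatureTable,
    evaluate_model,
    train_base_model,
    tune_hyperparameters,
)
from gliotex import io as gio


def plot_roc(model, test: FeatureTable, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve
    except ImportError:
        print("matplotlib not available; skipping ROC plot")
        return
    proba = model.predict_proba(test.features.to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(5, 4))
    for code, cls in enumerate(CLASSES):
        fpr, tpr, _ = roc_curve((test.labels == code).astype(int), proba[:, code])
        ax.plot(fpr, tpr, label=f"{cls} vs rest")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    print(f"ROC curves -> {path}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--tune-iters", type=int, default=20)
    parser.add_argument("--tune-folds", type=int, default=5)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    train = FeatureTable.from_dataframe(gio.read_table(args.results / "train.csv"))
    test = FeatureTable.from_dataframe(gio.read_table(args.results / "test.csv"))

    base, base_report = train_base_model(train, test, seed=args.seed)
    print(f"base model:  accuracy {base_report.accuracy_percent:.2f}% "
          f"(error {base_report.error_percent:.2f}%)")

    params, tuned_cv = tune_hyperparameters(
        train, method="random", k=args.tune_folds, seed=args.seed,
        n_iter=args.tune_iters,
    )
    tuned = params.build(seed=args.seed)
    tuned.fit(train.features.to_numpy(dtype=float), train.labels)
    tuned_report = evaluate_model(tuned, test)
    print(f"tuned model: accuracy {tuned_report.accuracy_percent:.2f}% "
          f"(error {tuned_report.error_percent:.2f}%); params {asdict(params)}")
    for cls in CLASSES:
        print(f"  {cls}: precision {tuned_report.precision[cls]:.2f}  "
              f"recall {tuned_report.recall[cls]:.2f}  "
              f"f1 {tuned_report.f1[cls]:.2f}  support {tuned_report.support[cls]}"
              + (f"  OVR AUC {tuned_report.ovr_auc[cls]:.4f}"
                 if cls in tuned_report.ovr_auc else ""))

    gio.write_json(args.results / "model_report.json", {
        "base": base_report.to_dict(),
        "tuned_params": asdict(params),
        "tuned_cv_accuracy": tuned_cv,
        "tuned": tuned_report.to_dict(),
    })
    pd.DataFrame(
        tuned_report.confusion,
        index=[f"true_{c}" for c in CLASSES],
        columns=[f"pred_{c}" for c in CLASSES],
    ).to_csv(args.results / "confusion_tuned.csv")
    plot_roc(tuned, test, args.results / "roc_tuned.png")


if __name__ == "__main__":
    main()
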