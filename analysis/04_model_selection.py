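#!/usr/bin/env python
"""Ten-fold cross-validation of seven classifiers, with and without SMOTE.

Reads results/features.csv and compares the balanced arm (the default
protocol's training fold from step 03) against an imbalanced arm prepared
identically but without oversampling. Writes results/cv_scores.csv with
mean fold accuracy and sd per algorithm and arm.
"""

import argparse
from pathlib import Path

import pandas as pd

from gliotex import FeatureTable, SmoteConfig, crossvalidate_algorithms, prepare
from gliotex import io as gio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--folds", type=int, default=10)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = FeatureTable.from_dataframe(gio.read_table(args.results / "features.csv"))
    arms = {}
    for arm, smote in (("with SMOTE", True), ("without SMOTE", False)):
        if smote:
            train, _, _, _ = prepare(table, mode="paper", split_seed=args.seed,
                                     smote_cfg=SmoteConfig(rng_seed=args.seed))
        else:
            # identical preparation, oversampling skipped
            from gliotex import (anova_f_scores, apply_standardizer,
                                 fit_standardizer, select_features, split_train_test)
            tr, _ = split_train_test(table, 0.30, seed=args.seed)
            tr = apply_standardizer(fit_standardizer(tr), tr)
            train, _ = select_features(anova_f_scores(tr), tr, drop_count=3)
        arms[arm] = crossvalidate_algorithms(train, k=args.folds, seed=args.seed)

    rows = []
    for arm, cv in arms.items():
        for name in cv.mean_accuracy:
            rows.append({"arm": arm, "algorithm": name,
                         "mean_accuracy": cv.mean_accuracy[name],
                         "sd": cv.sd_accuracy[name]})
    gio.write_table(args.results / "cv_scores.csv", pd.DataFrame(rows))

    for arm, cv in arms.items():
        print(f"{arm} (K={cv.k}):")
        for name in cv.mean_accuracy:
            print(f"  {name:30s} {cv.mean_accuracy[name]:.4f} ± {cv.sd_accuracy[name]:.4f}")
        print(f"  -> winner: {cv.winner}")


if __name__ == "__main__":
    main()
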