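#!/usr/bin/env python
"""Balance, split, standardize and ANOVA-select the feature table.

Reads results/features.csv (step 02). The default protocol mirrors the
reference study: SMOTE equalizes all classes to the majority size before a
stratified 70:30 split at random state 42, features are z-scored on the
training fold, and the three lowest-F features of a one-way ANOVA against
the class labels are dropped (16 -> 13). Writes results/train.csv,
results/test.csv and results/preparation.json.
"""

import argparse
from pathlib import Path

from gliotex import FeatureTable, SmoteConfig, prepare
from gliotex import io as gio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--mode", choices=["paper", "sound"], default="paper",
                        help="SMOTE before the split (paper) or on the train fold only")
    parser.add_argument("--scaler", choices=["zscore", "minmax"], default="zscore")
    parser.add_argument("--drop", type=int, default=3)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = FeatureTable.from_dataframe(gio.read_table(args.results / "features.csv"))
    train, test, params, anova = prepare(
        table, mode=args.mode, scaler=args.scaler, drop_count=args.drop,
        split_seed=args.seed, smote_cfg=SmoteConfig(rng_seed=args.seed),
    )
    gio.write_table(args.results / "train.csv", train.to_dataframe())
    gio.write_table(args.results / "test.csv", test.to_dataframe())
    gio.write_json(args.results / "preparation.json", {
        "mode": args.mode,
        "scaler": {"mode": params.mode, "feature_names": params.feature_names,
                   "center": params.center, "scale": params.scale,
                   "constant_features": params.constant_features},
        "anova_f_scores": anova.f_scores,
        "excluded_features": anova.excluded_features,
        "seed": args.seed,
    })

    print(f"train {train.n_rows} rows / test {test.n_rows} rows "
          f"(test supports {test.class_counts()})")
    print("ANOVA F scores (train fold):")
    for name, f in sorted(anova.f_scores.items(), key=lambda kv: -kv[1]):
        mark = "  [dropped]" if name in anova.excluded_features else ""
        print(f"  {name:20s} {f:10.4f}{mark}")


if __name__ == "__main__":
    main()
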