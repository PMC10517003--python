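"""End-to-end pipeline orchestration: simulate -> ADC -> features -> prepare -> model.

One :class:`RunConfig` (serializable JSON) plus one global seed determine
every stochastic choice in a run; the emitted :class:`RunManifest` records
the config snapshot and SHA-256 hashes of every file written, so a rerun
with the same config reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .adc import AdcMap, RoiMask, compute_adc_map
from .cohort import CLASS_CODES, CohortConfig, SliceRecord, generate_cohort
from .modeling import (
    crossvalidate_algorithms,
    evaluate_model,
    train_base_model,
    tune_hyperparameters,
)
from .pipeline import FeatureTable, SmoteConfig, prepare
from .texture import FEATURE_NAMES, extract_feature_vector

__all__ = [
    "RunConfig",
    "RunManifest",
    "extract_cohort_features",
    "features_from_files",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Every stage's knobs plus the single global seed."""

    seed: int = 42
    mode: str = "paper"            # SMOTE before split (paper) or train-only (sound)
    scaler: str = "zscore"
    drop_count: int = 3
    n_levels: int = 64
    symmetric_glcm: bool = False
    test_fraction: float = 0.30
    cv_folds: int = 10
    tune_method: str = "random"
    tune_iters: int = 100
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    out_dir: str = "results"

    def cohort_config(self) -> CohortConfig:
        cfg = CohortConfig(**self.cohort) if self.cohort else CohortConfig()
        cfg.rng_seed = self.seed
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timing_s: dict[str, float] = field(default_factory=dict)
    version: str = ""

    def record(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()


def extract_cohort_features(
    slices: list[SliceRecord],
    demographics: pd.DataFrame,
    n_levels: int = 64,
    symmetric: bool = False,
    from_dwi: bool = True,
) -> FeatureTable:
    """The 16-feature table of a cohort, one row per slice ROI.

    ``from_dwi`` recomputes the ADC map from the noisy DWI pair (the full
    measurement chain); otherwise the generator's ground-truth field is
    used directly.
    """
    demo = demographics.set_index("slice_id")
    rows, labels = [], []
    for rec in slices:
        adc = compute_adc_map(rec.dwi_pair) if from_dwi else rec.true_adc_field
        meta = demo.loc[rec.slice_id]
        rows.append(
            extract_feature_vector(
                adc,
                rec.roi,
                age=float(meta["age"]),
                gender=str(meta["gender"]),
                n_levels=n_levels,
                symmetric=symmetric,
            )
        )
        labels.append(CLASS_CODES[rec.who_class])
    return FeatureTable(
        features=pd.DataFrame(rows, columns=list(FEATURE_NAMES)),
        labels=np.array(labels),
    )


def features_from_files(
    image_dir: str | Path,
    mask_dir: str | Path,
    demographics_csv: str | Path,
    n_levels: int = 64,
    symmetric: bool = False,
) -> FeatureTable:
    """Real-data mode: ADC images + masks on disk plus a demographics CSV.

    Expects, per slice_id in the CSV, ``<slice_id>_adc`` and
    ``<slice_id>_mask`` files in NIfTI (.nii/.nii.gz) or 16-bit PNG.
    """
    demo = gio.read_table(demographics_csv)
    required = {"slice_id", "age", "gender", "who_class"}
    if not required.issubset(demo.columns):
        raise ValueError(f"demographics CSV must have columns {sorted(required)}")

    def find(folder: Path, stem: str) -> Path:
        for ext in (".nii.gz", ".nii", ".png"):
            p = folder / f"{stem}{ext}"
            if p.exists():
                return p
        raise FileNotFoundError(f"no {stem}.(nii.gz|nii|png) under {folder}")

    rows, labels = [], []
    for _, r in demo.iterrows():
        adc_path = find(Path(image_dir), f"{r['slice_id']}_adc")
        adc_vals = (
            gio.read_adc_png(adc_path) if adc_path.suffix == ".png" else gio.read_image(adc_path)
        )
        mask = gio.read_mask(find(Path(mask_dir), f"{r['slice_id']}_mask"))
        rows.append(
            extract_feature_vector(
                AdcMap(values=adc_vals),
                RoiMask(mask=mask),
                age=float(r["age"]),
                gender=str(r["gender"]),
                n_levels=n_levels,
                symmetric=symmetric,
            )
        )
        labels.append(CLASS_CODES[str(r["who_class"])])
    return FeatureTable(
        features=pd.DataFrame(rows, columns=list(FEATURE_NAMES)),
        labels=np.array(labels),
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in order and write all artifacts under ``out_dir``."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__)

    t0 = time.perf_counter()
    cohort_cfg = config.cohort_config()
    slices, demo = generate_cohort(cohort_cfg)
    gio.write_table(out / "demographics.csv", demo)
    manifest.record(out / "demographics.csv")
    manifest.timing_s["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table = extract_cohort_features(
        slices, demo, n_levels=config.n_levels, symmetric=config.symmetric_glcm
    )
    gio.write_table(out / "features.csv", table.to_dataframe())
    manifest.record(out / "features.csv")
    manifest.timing_s["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    train, test, scaler_params, anova = prepare(
        table,
        mode=config.mode,
        scaler=config.scaler,
        drop_count=config.drop_count,
        test_fraction=config.test_fraction,
        split_seed=config.seed,
        smote_cfg=SmoteConfig(rng_seed=config.seed),
    )
    gio.write_table(out / "train.csv", train.to_dataframe())
    gio.write_table(out / "test.csv", test.to_dataframe())
    gio.write_json(
        out / "preparation.json",
        {
            "scaler": {
                "mode": scaler_params.mode,
                "feature_names": scaler_params.feature_names,
                "center": scaler_params.center,
                "scale": scaler_params.scale,
                "constant_features": scaler_params.constant_features,
            },
            "anova_f_scores": anova.f_scores,
            "excluded_features": anova.excluded_features,
            "seed": config.seed,
        },
    )
    for f in ("train.csv", "test.csv", "preparation.json"):
        manifest.record(out / f)
    manifest.timing_s["prepare"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cv = crossvalidate_algorithms(train, k=config.cv_folds, seed=config.seed)
    base_model, base_report = train_base_model(train, test, seed=config.seed)
    tuned_params, tuned_cv = tune_hyperparameters(
        train,
        method=config.tune_method,
        k=config.cv_folds,
        seed=config.seed,
        n_iter=config.tune_iters,
    )
    tuned_model = tuned_params.build(seed=config.seed)
    tuned_model.fit(train.features.to_numpy(dtype=float), train.labels)
    tuned_report = evaluate_model(tuned_model, test)
    gio.write_json(
        out / "model_report.json",
        {
            "cv": {"k": cv.k, "mean": cv.mean_accuracy, "sd": cv.sd_accuracy,
                   "winner": cv.winner},
            "base": base_report.to_dict() if base_report else None,
            "tuned_params": asdict(tuned_params),
            "tuned_cv_accuracy": tuned_cv,
            "tuned": tuned_report.to_dict(),
        },
    )
    manifest.record(out / "model_report.json")
    manifest.timing_s["model"] = time.perf_counter() - t0

    gio.write_json(out / "manifest.json", asdict(manifest))
    return manifest
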