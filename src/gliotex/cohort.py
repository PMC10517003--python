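"""Synthetic DWI phantom cohort with class-dependent diffusivity and texture.

No public dataset exists for the study design this pipeline targets, so the
generator emulates its statistical structure: an imbalanced three-class
cohort of 2D slice pairs (b=0 and b=1000 s/mm^2) with elliptical tumor ROIs
drawn over smooth Gaussian-random-field ADC textures. Aggressive tumors get
lower mean diffusivity (higher cellularity) and shorter spatial correlation
length (more heterogeneous texture); indolent ones higher, smoother fields.

The generative chain per slice is

    ADC field  (GRF: class mean + subject offset + correlated texture)
      -> DWI pair  S_b = S_0 * exp(-b * ADC) + Gaussian noise
      -> feature extraction downstream recovers the texture statistics.

Everything is driven by one integer seed; a fixed seed yields a
bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .adc import AdcMap, DwiSlicePair, RoiMask

__all__ = [
    "CLASSES",
    "CLASS_CODES",
    "CohortConfig",
    "SubjectRecord",
    "SliceRecord",
    "sample_demographics",
    "simulate_adc_texture_field",
    "synthesize_dwi_pair",
    "generate_cohort",
]

#: WHO grade groups, in label-code order 0/1/2.
CLASSES: tuple[str, ...] = ("GBM", "HGG", "LGG")
CLASS_CODES: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass
class CohortConfig:
    """Study-design parameters of the phantom cohort.

    Defaults reproduce the reference study composition: 88 subjects
    (57 male / 31 female, ages 8-90) contributing 722 slices split
    431/182/109 across GBM/HGG/LGG, imaged at 124x124 with b = 0 and
    1000 s/mm^2. Class ADC means sit in the physiological glioma range
    (GBM lowest), marginal sds and correlation lengths encode the
    class-dependent texture heterogeneity.
    """

    n_subjects: int = 88
    n_male: int = 57
    n_female: int = 31
    age_range: tuple[int, int] = (8, 90)
    slices_per_class: dict[str, int] = field(
        default_factory=lambda: {"GBM": 431, "HGG": 182, "LGG": 109}
    )
    image_shape: tuple[int, int] = (124, 124)
    b_values: tuple[float, ...] = (0.0, 1000.0)
    class_adc_mean: dict[str, float] = field(
        default_factory=lambda: {"GBM": 0.80e-3, "HGG": 1.00e-3, "LGG": 1.30e-3}
    )
    class_adc_sd: dict[str, float] = field(
        default_factory=lambda: {"GBM": 0.22e-3, "HGG": 0.18e-3, "LGG": 0.15e-3}
    )
    class_texture_corr_length: dict[str, float] = field(
        default_factory=lambda: {"GBM": 2.0, "HGG": 3.0, "LGG": 4.0}
    )
    subject_adc_offset_sd: float = 0.05e-3  # per-subject shift of the class mean
    s0_intensity: float = 1000.0
    noise_sd: float = 5.0
    roi_area_range: tuple[int, int] = (80, 600)
    rois_per_slice: int = 1
    age_class_shift: float = 0.0  # optional yrs/class-code trend, 0 = no age signal
    rng_seed: int = 42

    def validate(self) -> None:
        if self.n_male + self.n_female != self.n_subjects:
            raise ConfigurationError("n_male + n_female must equal n_subjects")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range low must be below high")
        if set(self.slices_per_class) != set(CLASSES):
            raise ConfigurationError(f"slices_per_class must cover {CLASSES}")
        if any(v < 1 for v in self.slices_per_class.values()):
            raise ConfigurationError("all slice counts must be >= 1")
        if any(self.class_adc_mean[c] <= 0 for c in CLASSES):
            raise ConfigurationError("class ADC means must be positive")
        if any(self.class_adc_sd[c] < 0 for c in CLASSES):
            raise ConfigurationError("class ADC sds must be non-negative")
        if self.n_subjects < len(CLASSES):
            raise ConfigurationError("need at least one subject per class")
        if any(b < 0 for b in self.b_values):
            raise ConfigurationError("b-values must be non-negative")
        if self.rois_per_slice < 1:
            raise ConfigurationError("rois_per_slice must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        cfg = cls(**d)
        for key in ("age_range", "image_shape", "b_values", "roi_area_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


@dataclass
class SubjectRecord:
    subject_id: str
    age: int
    gender: str
    who_class: str


@dataclass
class SliceRecord:
    """One labeled slice: DWI pair, ROI mask and the generating ADC field."""

    slice_id: str
    subject_id: str
    who_class: str
    dwi_pair: DwiSlicePair
    roi: RoiMask
    true_adc_field: AdcMap


def sample_demographics(config: CohortConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    """Draw the subject roster: ids, ages, genders and WHO class assignment.

    Subjects are allocated to classes proportionally to the configured slice
    counts (each class gets at least one subject); ages are uniform over the
    configured range, genders drawn to hit the configured counts exactly.
    """
    config.validate()

    total_slices = sum(config.slices_per_class.values())
    # proportional allocation with a floor of 1 subject per class
    alloc = {c: max(1, round(config.n_subjects * config.slices_per_class[c] / total_slices))
             for c in CLASSES}
    # repair rounding drift on the largest class
    drift = config.n_subjects - sum(alloc.values())
    largest = max(CLASSES, key=lambda c: config.slices_per_class[c])
    alloc[largest] += drift
    if alloc[largest] < 1:
        raise ConfigurationError("cannot allocate at least one subject per class")

    genders = np.array(["male"] * config.n_male + ["female"] * config.n_female)
    rng.shuffle(genders)

    classes: list[str] = []
    for c in CLASSES:
        classes.extend([c] * alloc[c])
    classes_arr = np.array(classes)
    rng.shuffle(classes_arr)

    lo, hi = config.age_range
    records = []
    for idx in range(config.n_subjects):
        who = str(classes_arr[idx])
        age = int(rng.integers(lo, hi + 1))
        if config.age_class_shift:
            age = int(np.clip(age + config.age_class_shift * CLASS_CODES[who], lo, hi))
        records.append(
            SubjectRecord(
                subject_id=f"sub-{idx + 1:03d}",
                age=age,
                gender=str(genders[idx]),
                who_class=who,
            )
        )
    return records


def _elliptical_mask(
    shape: tuple[int, int],
    rng: np.random.Generator,
    area_range: tuple[int, int],
    max_tries: int = 50,
) -> np.ndarray:
    """A random rotated ellipse whose pixel area falls in ``area_range``."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    for _ in range(max_tries):
        a = rng.uniform(5.0, 15.0)
        b = rng.uniform(5.0, 15.0)
        theta = rng.uniform(0, np.pi)
        margin = max(a, b) + 1
        if 2 * margin >= min(rows, cols):
            continue
        cy = rng.uniform(margin, rows - margin)
        cx = rng.uniform(margin, cols - margin)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if area_range[0] <= mask.sum() <= area_range[1]:
            return mask
    raise RuntimeError("could not draw an ellipse with the requested area")


def simulate_adc_texture_field(
    who_class: str,
    config: CohortConfig,
    rng: np.random.Generator,
    mean_shift: float = 0.0,
) -> tuple[AdcMap, RoiMask]:
    """A Gaussian-random-field ADC texture with an elliptical tumor ROI.

    The field has marginal mean ``class_adc_mean + mean_shift``, marginal sd
    ``class_adc_sd`` and isotropic correlation length
    ``class_texture_corr_length`` (pixels), obtained by Gaussian-smoothing
    white noise and rescaling to the target sd. Values are clipped positive.

    ``mean_shift`` carries the per-subject offset so slices of one subject
    share a diffusivity level.
    """
    if who_class not in CLASS_CODES:
        raise ValueError(f"unknown class {who_class!r}")
    mean = config.class_adc_mean[who_class] + mean_shift
    sd = config.class_adc_sd[who_class]
    corr = config.class_texture_corr_length[who_class]
    if mean <= 0:
        raise ValueError("effective class ADC mean must be positive")

    white = rng.standard_normal(config.image_shape)
    if sd > 0:
        smooth = gaussian_filter(white, sigma=corr, mode="wrap")
        smooth = smooth / smooth.std()
        values = mean + sd * smooth
    else:
        values = np.full(config.image_shape, mean)
    values = np.clip(values, 1e-6, None)

    mask = _elliptical_mask(config.image_shape, rng, config.roi_area_range)
    return AdcMap(values=values), RoiMask(mask=mask)


def synthesize_dwi_pair(
    adc_field: AdcMap,
    config: CohortConfig,
    rng: np.random.Generator,
) -> DwiSlicePair:
    """Forward-model a DWI pair from a ground-truth ADC field.

    Per pixel ``S_b = S_0 * exp(-b * ADC)`` plus additive Gaussian noise of
    sd ``noise_sd`` on every image (including b=0). With ``noise_sd = 0``
    the pair inverts exactly under the ADC estimator.
    """
    if any(b < 0 for b in config.b_values):
        raise ValueError("b-values must be non-negative")
    if (adc_field.values <= 0).any():
        raise ValueError("ADC field must be positive everywhere")

    s0_clean = np.full(adc_field.shape, config.s0_intensity)

    def noisy(img: np.ndarray) -> np.ndarray:
        if config.noise_sd > 0:
            return img + rng.normal(0.0, config.noise_sd, img.shape)
        return img

    s0 = noisy(s0_clean)
    sb_images = [
        (b, noisy(s0_clean * np.exp(-b * adc_field.values)))
        for b in config.b_values
        if b > 0
    ]
    if not sb_images:
        raise ValueError("at least one b > 0 is required")
    return DwiSlicePair(s0_image=s0, sb_images=sb_images)


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[SliceRecord], pd.DataFrame]:
    """Generate the full phantom cohort from one seed.

    Returns the slice records (counts per class exactly as configured, each
    slice linked to a subject of its class round-robin) and a demographics
    table with columns slice_id, subject_id, age, gender, who_class.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    subjects = sample_demographics(config, rng)
    by_class: dict[str, list[SubjectRecord]] = {c: [] for c in CLASSES}
    for s in subjects:
        by_class[s.who_class].append(s)
    offsets = {
        s.subject_id: rng.normal(0.0, config.subject_adc_offset_sd) for s in subjects
    }

    slices: list[SliceRecord] = []
    rows = []
    for who in CLASSES:
        pool = by_class[who]
        for k in range(config.slices_per_class[who]):
            subject = pool[k % len(pool)]
            for r in range(config.rois_per_slice):
                adc, roi = simulate_adc_texture_field(
                    who, config, rng, mean_shift=offsets[subject.subject_id]
                )
                pair = synthesize_dwi_pair(adc, config, rng)
                sid = f"{who.lower()}-{k + 1:04d}" + (
                    f"-roi{r + 1}" if config.rois_per_slice > 1 else ""
                )
                slices.append(
                    SliceRecord(
                        slice_id=sid,
                        subject_id=subject.subject_id,
                        who_class=who,
                        dwi_pair=pair,
                        roi=roi,
                        true_adc_field=adc,
                    )
                )
                rows.append(
                    {
                        "slice_id": sid,
                        "subject_id": subject.subject_id,
                        "age": subject.age,
                        "gender": subject.gender,
                        "who_class": who,
                    }
                )
    return slices, pd.DataFrame(rows)
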