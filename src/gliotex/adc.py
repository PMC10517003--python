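"""Apparent diffusion coefficient (ADC) maps from diffusion-weighted image pairs.

The ADC quantifies water diffusivity (mm^2/s) from the mono-exponential
signal decay of DWI across b-values:

    S_b = S_0 * exp(-b * ADC)   =>   ADC = -ln(S_b / S_0) / b

With several diffusion-weighted images the per-b estimates are averaged so
the result keeps mm^2/s units regardless of how many b-values contributed.
Pixels with non-positive signal in either image cannot support the log-ratio
and are flagged invalid (ADC set to 0, excluded from the validity mask).

Grey-level quantization of ROI values (needed for co-occurrence matrices)
lives here too: per-ROI min--max linear binning into ``n_levels`` equal-width
bins, so texture statistics are invariant to any affine rescaling of the
underlying diffusivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DwiSlicePair",
    "AdcMap",
    "RoiMask",
    "QuantizedRoi",
    "compute_adc_map",
    "quantize_roi",
]


@dataclass
class DwiSlicePair:
    """One b=0 image and >=1 diffusion-weighted images of the same slice."""

    s0_image: np.ndarray
    sb_images: list[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        self.s0_image = np.asarray(self.s0_image, dtype=float)
        if self.s0_image.ndim != 2:
            raise ValueError("s0_image must be a 2D array")
        if not self.sb_images:
            raise ValueError("at least one diffusion-weighted (b>0) image is required")
        checked = []
        for b, img in self.sb_images:
            img = np.asarray(img, dtype=float)
            if b <= 0:
                raise ValueError(f"b-value must be positive, got {b}")
            if img.shape != self.s0_image.shape:
                raise ValueError(
                    f"shape mismatch: b={b} image {img.shape} vs b=0 {self.s0_image.shape}"
                )
            checked.append((float(b), img))
        self.sb_images = checked

    @property
    def n(self) -> int:
        return len(self.sb_images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.s0_image.shape


@dataclass
class AdcMap:
    """2D diffusivity map in mm^2/s with a validity mask."""

    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ADC values must be a 2D array")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("validity mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RoiMask:
    """Boolean tumor mask restricting all feature computation."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be a 2D array")
        if self.pixel_count < 1:
            raise ValueError("ROI mask is empty")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class QuantizedRoi:
    """Integer grey levels over a ROI; off-ROI pixels are marked ``INVALID``."""

    INVALID = -1

    levels: np.ndarray
    n_levels: int
    quantization_range: tuple[float, float]

    @property
    def valid_mask(self) -> np.ndarray:
        return self.levels != self.INVALID


def compute_adc_map(pair: DwiSlicePair) -> AdcMap:
    """Estimate the ADC map of one slice from its DWI pair.

    Per pixel ``ADC = mean_i[-ln(S_i/S_0)/b_i]``, positive where the signal
    attenuates with increasing b. Pixels with ``S_0 <= 0`` or any
    ``S_i <= 0`` are invalid: value 0, masked out.

    Parameters
    ----------
    pair
        The b=0 image together with its diffusion-weighted images.

    Returns
    -------
    AdcMap
        Diffusivities in mm^2/s with ``valid`` False on degenerate pixels.
    """
    s0 = pair.s0_image
    valid = s0 > 0
    for _, img in pair.sb_images:
        valid &= img > 0

    acc = np.zeros_like(s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        for b, img in pair.sb_images:
            ratio = np.where(valid, img / np.where(valid, s0, 1.0), 1.0)
            acc += -np.log(ratio) / b
    values = np.where(valid, acc / pair.n, 0.0)
    return AdcMap(values=values, valid=valid)


def quantize_roi(adc: AdcMap, roi: RoiMask, n_levels: int = 64) -> QuantizedRoi:
    """Bin ROI diffusivities into ``n_levels`` equal-width grey levels.

    The binning runs from the ROI minimum to the ROI maximum (invalid pixels
    excluded first), the maximum mapping to level ``n_levels - 1``. A
    constant ROI maps entirely to level 0. The mapping is monotone, so any
    order statistics of the levels follow those of the diffusivities.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if roi.shape != adc.shape:
        raise ValueError("ROI and ADC map shapes differ")
    inside = roi.mask & adc.valid
    if not inside.any():
        raise ValueError("ROI contains no valid pixels")

    vals = adc.values[inside]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.full(adc.shape, QuantizedRoi.INVALID, dtype=np.int64)
    if hi > lo:
        scaled = (adc.values[inside] - lo) / (hi - lo) * n_levels
        levels[inside] = np.clip(scaled.astype(np.int64), 0, n_levels - 1)
    else:
        levels[inside] = 0
    return QuantizedRoi(levels=levels, n_levels=int(n_levels), quantization_range=(lo, hi))
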