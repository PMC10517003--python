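"""ROI texture features: intensity moments and grey-level co-occurrence statistics.

Two feature families are computed inside a tumor ROI of an ADC map:

* first/higher-order moments of the diffusivity histogram — mean ADC,
  standardized skewness (m3 / m2^1.5) and non-excess kurtosis (m4 / m2^2,
  so a normal population scores 3);
* Haralick-style statistics of the grey-level co-occurrence matrix (GLCM)
  accumulated over the four unit-distance orientations 0deg, 45deg, 90deg,
  135deg and summed: marginal means and variances, energy, entropy (nats),
  contrast, homogeneity, correlation, cluster shade and cluster prominence.

The GLCM is, by default, NOT symmetrized: each ordered neighbour pair
(reference pixel, offset pixel) is counted once, which is why the row- and
column-marginal means/variances are reported separately. A ``symmetric``
flag restores the common symmetrized convention, under which the two
marginals coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adc import AdcMap, QuantizedRoi, RoiMask

__all__ = [
    "DEFAULT_OFFSETS",
    "FEATURE_NAMES",
    "MomentSet",
    "GlcmMatrix",
    "GlcmFeatures",
    "roi_moments",
    "build_glcm",
    "glcm_features",
    "extract_feature_vector",
]

#: Unit-distance offsets for the 0deg, 45deg, 90deg and 135deg orientations
#: in (row, col) convention with the origin at the top-left.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

#: The 16 features of one slice row, in canonical order (14 image-derived
#: plus the two demographics).
FEATURE_NAMES: tuple[str, ...] = (
    "Mean ADC",
    "Skewness",
    "Kurtosis",
    "GLCM mean 1",
    "GLCM mean 2",
    "GLCM variance 1",
    "GLCM variance 2",
    "Energy",
    "Entropy",
    "Contrast",
    "Homogeneity",
    "Correlation",
    "Prominence",
    "Shade",
    "Patients' age",
    "Patients' gender",
)


@dataclass
class MomentSet:
    """Histogram moments of the ROI diffusivities."""

    mean_adc: float
    variance: float
    skewness: float
    kurtosis: float
    degenerate: bool = False  # True when the ROI had zero variance

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance cannot be negative")


@dataclass
class GlcmMatrix:
    """Normalized co-occurrence probability matrix with its provenance."""

    probabilities: np.ndarray
    n_levels: int
    offsets_used: tuple[tuple[int, int], ...]
    pair_count: int
    symmetric: bool = False

    def __post_init__(self) -> None:
        P = np.asarray(self.probabilities, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("GLCM must be square")
        if (P < 0).any():
            raise ValueError("GLCM probabilities must be non-negative")
        if abs(P.sum() - 1.0) > 1e-12:
            raise ValueError("GLCM probabilities must sum to 1")
        if self.pair_count < 1:
            raise ValueError("GLCM must be accumulated from at least one pair")
        self.probabilities = P


@dataclass
class GlcmFeatures:
    mean_i: float
    mean_j: float
    variance_i: float
    variance_j: float
    energy: float
    entropy: float
    contrast: float
    homogeneity: float
    correlation: float
    cluster_shade: float
    cluster_prominence: float
    correlation_degenerate: bool = False  # zero marginal variance, correlation forced 0


def roi_moments(adc: AdcMap, roi: RoiMask) -> MomentSet:
    """Mean and standardized higher moments of the valid ROI diffusivities.

    Central moments use equal pixel weights 1/N. A zero-variance ROI cannot
    support standardized moments; skewness and kurtosis are then reported as
    0 with ``degenerate=True`` rather than raising, so constant phantoms run
    through the pipeline.
    """
    if roi.shape != adc.shape:
        raise ValueError("ROI and ADC map shapes differ")
    vals = adc.values[roi.mask & adc.valid]
    if vals.size < 3:
        raise ValueError("ROI must contain at least 3 valid pixels")
    mean = float(vals.mean())
    centered = vals - mean
    m2 = float(np.mean(centered**2))
    # a constant ROI can leave a denormal m2 through summation round-off;
    # the range being zero is the authoritative degeneracy signal
    if m2 == 0.0 or vals.max() == vals.min():
        return MomentSet(mean_adc=mean, variance=0.0, skewness=0.0, kurtosis=0.0, degenerate=True)
    m3 = float(np.mean(centered**3))
    m4 = float(np.mean(centered**4))
    return MomentSet(
        mean_adc=mean,
        variance=m2,
        skewness=m3 / m2**1.5,
        kurtosis=m4 / m2**2,
    )


def build_glcm(
    q: QuantizedRoi,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = False,
) -> GlcmMatrix:
    """Accumulate the co-occurrence matrix of a quantized ROI.

    For every offset (dr, dc) and every pixel p with both p and p+(dr, dc)
    valid and inside the ROI, the count at (level(p), level(p+(dr, dc))) is
    incremented. With ``symmetric`` each pair is also counted reversed.
    Counts from all offsets are summed before normalizing to probabilities.

    Raises
    ------
    ValueError
        If no valid in-ROI pixel pair exists for any offset (degenerate
        one-pixel or fully disconnected ROI).
    """
    levels = q.levels
    n = q.n_levels
    counts = np.zeros((n, n), dtype=np.int64)
    rows, cols = levels.shape
    for dr, dc in offsets:
        r0 = max(0, -dr)
        r1 = rows - max(0, dr)
        c0 = max(0, -dc)
        c1 = cols - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            continue
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (a != QuantizedRoi.INVALID) & (b != QuantizedRoi.INVALID)
        if not ok.any():
            continue
        np.add.at(counts, (a[ok], b[ok]), 1)
    if symmetric:
        counts = counts + counts.T
    pair_count = int(counts.sum())
    if pair_count == 0:
        raise ValueError("degenerate ROI: no valid in-ROI pixel pair for the given offsets")
    return GlcmMatrix(
        probabilities=counts / pair_count,
        n_levels=n,
        offsets_used=tuple(offsets),
        pair_count=pair_count,
        symmetric=symmetric,
    )


def glcm_features(glcm: GlcmMatrix) -> GlcmFeatures:
    """The nine co-occurrence statistics plus the two marginal mean/variance pairs.

    Entropy uses the natural logarithm with the convention 0*ln(0) = 0.
    Correlation is reported as 0 (flagged) when either marginal variance
    vanishes, which happens exactly for single-entry matrices.
    """
    P = glcm.probabilities
    n = glcm.n_levels
    i = np.arange(n, dtype=float)[:, None]
    j = np.arange(n, dtype=float)[None, :]

    mean_i = float((i * P).sum())
    mean_j = float((j * P).sum())
    var_i = float((P * (i - mean_i) ** 2).sum())
    var_j = float((P * (j - mean_j) ** 2).sum())

    energy = float((P**2).sum())
    nz = P > 0
    entropy = float(-(P[nz] * np.log(P[nz])).sum())
    contrast = float((P * (i - j) ** 2).sum())
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())

    denom = var_i * var_j
    degenerate = denom <= 0.0
    if degenerate:
        correlation = 0.0
    else:
        correlation = float((P * (i - mean_i) * (j - mean_j)).sum() / np.sqrt(denom))

    dev = i + j - mean_i - mean_j
    shade = float((dev**3 * P).sum())
    prominence = float((dev**4 * P).sum())

    return GlcmFeatures(
        mean_i=mean_i,
        mean_j=mean_j,
        variance_i=var_i,
        variance_j=var_j,
        energy=energy,
        entropy=entropy,
        contrast=contrast,
        homogeneity=homogeneity,
        correlation=correlation,
        cluster_shade=shade,
        cluster_prominence=prominence,
        correlation_degenerate=degenerate,
    )


def extract_feature_vector(
    adc: AdcMap,
    roi: RoiMask,
    age: float,
    gender: str | int,
    n_levels: int = 64,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = False,
) -> dict[str, float]:
    """One ordered 16-feature row for a slice: 14 image features + demographics.

    Gender is binarized male=1 / female=0 (integers pass through unchanged).
    Returns a dict keyed by :data:`FEATURE_NAMES`, in that order.
    """
    from .adc import quantize_roi

    if isinstance(gender, str):
        g = gender.strip().lower()
        if g not in {"male", "female"}:
            raise ValueError(f"gender must be 'male' or 'female', got {gender!r}")
        gender_code = 1.0 if g == "male" else 0.0
    else:
        gender_code = float(gender)

    moments = roi_moments(adc, roi)
    q = quantize_roi(adc, roi, n_levels=n_levels)
    feats = glcm_features(build_glcm(q, offsets=offsets, symmetric=symmetric))

    values = (
        moments.mean_adc,
        moments.skewness,
        moments.kurtosis,
        feats.mean_i,
        feats.mean_j,
        feats.variance_i,
        feats.variance_j,
        feats.energy,
        feats.entropy,
        feats.contrast,
        feats.homogeneity,
        feats.correlation,
        feats.cluster_prominence,
        feats.cluster_shade,
        float(age),
        gender_code,
    )
    return dict(zip(FEATURE_NAMES, values))
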