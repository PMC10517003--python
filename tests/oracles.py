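"""Independent brute-force reference implementations used only by the tests.

Deliberately naive (explicit double loops, exhaustive enumeration) so they
share no code path with the vectorized implementations they check.
"""

import numpy as np

INVALID = -1


def naive_glcm_counts(levels: np.ndarray, n_levels: int, offsets, symmetric=False):
    rows, cols = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            if levels[r, c] == INVALID:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and levels[r2, c2] != INVALID:
                    counts[levels[r, c], levels[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def naive_glcm_features(P: np.ndarray) -> dict:
    n = P.shape[0]
    mean_i = sum(i * P[i, j] for i in range(n) for j in range(n))
    mean_j = sum(j * P[i, j] for i in range(n) for j in range(n))
    var_i = sum(P[i, j] * (i - mean_i) ** 2 for i in range(n) for j in range(n))
    var_j = sum(P[i, j] * (j - mean_j) ** 2 for i in range(n) for j in range(n))
    energy = sum(P[i, j] ** 2 for i in range(n) for j in range(n))
    entropy = sum(-P[i, j] * np.log(P[i, j]) for i in range(n) for j in range(n) if P[i, j] > 0)
    contrast = sum(P[i, j] * (i - j) ** 2 for i in range(n) for j in range(n))
    homogeneity = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    denom = var_i * var_j
    if denom > 0:
        correlation = sum(
            P[i, j] * (i - mean_i) * (j - mean_j) for i in range(n) for j in range(n)
        ) / np.sqrt(denom)
    else:
        correlation = 0.0
    shade = sum((i + j - mean_i - mean_j) ** 3 * P[i, j] for i in range(n) for j in range(n))
    prominence = sum((i + j - mean_i - mean_j) ** 4 * P[i, j] for i in range(n) for j in range(n))
    return {
        "mean_i": mean_i, "mean_j": mean_j, "variance_i": var_i, "variance_j": var_j,
        "energy": energy, "entropy": entropy, "contrast": contrast,
        "homogeneity": homogeneity, "correlation": correlation,
        "cluster_shade": shade, "cluster_prominence": prominence,
    }


def naive_moments(values: np.ndarray) -> dict:
    vals = [float(v) for v in np.ravel(values)]
    n = len(vals)
    mean = sum(vals) / n
    m2 = sum((v - mean) ** 2 for v in vals) / n
    m3 = sum((v - mean) ** 3 for v in vals) / n
    m4 = sum((v - mean) ** 4 for v in vals) / n
    return {
        "mean": mean,
        "variance": m2,
        "skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
    }


def naive_anova_f(x: np.ndarray, labels: np.ndarray) -> float:
    groups = [x[labels == c] for c in np.unique(labels)]
    n = len(x)
    k = len(groups)
    grand = sum(float(v) for v in x) / n
    ssb = sum(len(g) * (float(np.mean(g)) - grand) ** 2 for g in groups)
    ssw = sum(float(sum((v - np.mean(g)) ** 2 for v in g)) for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


def naive_ovr_auc(y_true: np.ndarray, scores: np.ndarray, cls: int) -> float:
    """AUC for class `cls` vs rest by exhaustive pairwise comparison."""
    pos = scores[y_true == cls]
    neg = scores[y_true != cls]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
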