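import numpy as np
import pandas as pd
import pytest

import gliotex as gt


@pytest.fixture(scope="session")
def small_config() -> gt.CohortConfig:
    """A reduced cohort for unit tests: same structure, desk-scale counts."""
    return gt.CohortConfig(
        n_subjects=12,
        n_male=8,
        n_female=4,
        slices_per_class={"GBM": 30, "HGG": 20, "LGG": 15},
        image_shape=(64, 64),
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return gt.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort) -> gt.FeatureTable:
    slices, demo = small_cohort
    return gt.extract_cohort_features(slices, demo, n_levels=32)


@pytest.fixture(scope="session")
def default_cohort_features() -> gt.FeatureTable:
    """Feature table of the full default cohort (722 slices, 431/182/109)."""
    slices, demo = gt.generate_cohort(gt.CohortConfig())
    return gt.extract_cohort_features(slices, demo)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def random_feature_table(
    rng: np.random.Generator,
    n_per_class: tuple[int, int, int] = (20, 15, 10),
    n_features: int = 6,
    class_shift: float = 0.0,
) -> gt.FeatureTable:
    """Random numeric table with optional per-class mean shift on all features."""
    rows, labels = [], []
    for code, n in enumerate(n_per_class):
        rows.append(rng.normal(code * class_shift, 1.0, size=(n, n_features)))
        labels.extend([code] * n)
    X = np.vstack(rows)
    return gt.FeatureTable(
        features=pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)]),
        labels=np.array(labels),
    )
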