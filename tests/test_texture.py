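"""ROI moments and GLCM texture statistics against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import gliotex as gt
from gliotex.texture import DEFAULT_OFFSETS

from .oracles import naive_glcm_counts, naive_glcm_features, naive_moments


def full_roi(shape):
    return gt.RoiMask(mask=np.ones(shape, bool))


def adc_of(values):
    return gt.AdcMap(values=np.asarray(values, dtype=float))


class TestRoiMoments:
    def test_symmetric_sample_has_zero_skewness(self):
        m = gt.roi_moments(adc_of([[1, 2, 3, 4, 5]]), full_roi((1, 5)))
        assert m.skewness == pytest.approx(0.0, abs=1e-12)

    def test_bernoulli_sample_brute_force(self):
        # {0,0,0,1}: mean 1/4, m2 = 3/16, skew = 2/sqrt(3), kurt = 7/3
        m = gt.roi_moments(adc_of([[0, 0], [0, 1]]), full_roi((2, 2)))
        assert m.mean_adc == pytest.approx(0.25)
        assert m.variance == pytest.approx(0.1875)
        assert m.skewness == pytest.approx(2 / np.sqrt(3), rel=1e-12)
        assert m.kurtosis == pytest.approx(7 / 3, rel=1e-12)

    def test_large_normal_sample_kurtosis_near_three(self):
        x = np.random.default_rng(2024).standard_normal((1000, 1000))
        m = gt.roi_moments(adc_of(x), full_roi(x.shape))
        assert m.kurtosis == pytest.approx(3.0, abs=0.05)
        assert m.skewness == pytest.approx(0.0, abs=0.05)

    def test_matches_scipy_and_naive_oracle_on_random_samples(self, rng):
        for _ in range(20):
            x = rng.gamma(2.0, 1.0, size=(6, 7))
            m = gt.roi_moments(adc_of(x), full_roi(x.shape))
            ref = naive_moments(x)
            assert m.skewness == pytest.approx(ref["skewness"], rel=1e-12)
            assert m.kurtosis == pytest.approx(ref["kurtosis"], rel=1e-12)
            assert m.skewness == pytest.approx(stats.skew(x.ravel()), rel=1e-9)
            assert m.kurtosis == pytest.approx(
                stats.kurtosis(x.ravel(), fisher=False), rel=1e-9
            )
            # Pearson inequality for any sample
            assert m.kurtosis >= m.skewness**2 + 1 - 1e-12

    def test_zero_variance_flagged_not_crashing(self):
        m = gt.roi_moments(adc_of(np.full((3, 3), 1.1e-3)), full_roi((3, 3)))
        assert m.degenerate and m.skewness == 0.0 and m.kurtosis == 0.0

    def test_too_small_roi_rejected(self):
        with pytest.raises(ValueError):
            gt.roi_moments(adc_of([[1.0, 2.0]]), full_roi((1, 2)))


def quantized(levels, n_levels):
    return gt.QuantizedRoi(
        levels=np.asarray(levels, dtype=np.int64),
        n_levels=n_levels,
        quantization_range=(0.0, 1.0),
    )


class TestBuildGlcm:
    def test_constant_roi_single_entry(self):
        g = gt.build_glcm(quantized(np.zeros((3, 3)), 4))
        assert g.probabilities[0, 0] == 1.0
        assert g.probabilities.sum() == 1.0

    def test_hand_enumerated_2x2(self):
        # levels [[0,1],[0,1]]: exhaustive neighbour pairs over the 4 offsets
        g = gt.build_glcm(quantized([[0, 1], [0, 1]], 2))
        ref = naive_glcm_counts(np.array([[0, 1], [0, 1]]), 2, DEFAULT_OFFSETS)
        assert g.pair_count == ref.sum()
        np.testing.assert_allclose(g.probabilities, ref / ref.sum())

    def test_symmetric_flag_gives_transpose_symmetry(self, rng):
        levels = rng.integers(0, 8, size=(10, 10))
        g = gt.build_glcm(quantized(levels, 8), symmetric=True)
        np.testing.assert_allclose(g.probabilities, g.probabilities.T)

    def test_matches_naive_oracle_with_irregular_roi(self, rng):
        for _ in range(25):
            levels = rng.integers(0, 6, size=(9, 9))
            levels[rng.random((9, 9)) < 0.3] = gt.QuantizedRoi.INVALID
            if (levels != gt.QuantizedRoi.INVALID).sum() < 4:
                continue
            ref = naive_glcm_counts(levels, 6, DEFAULT_OFFSETS)
            if ref.sum() == 0:
                continue
            g = gt.build_glcm(quantized(levels, 6))
            np.testing.assert_allclose(g.probabilities, ref / ref.sum(), atol=1e-15)

    def test_matches_skimage_on_full_rectangles(self, rng):
        """Cross-check against an independent library implementation."""
        graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
        img = rng.integers(0, 16, size=(20, 24), dtype=np.uint8)
        # symmetrized accumulation is orientation-sign agnostic, so the two
        # libraries' opposite per-orientation offset conventions coincide
        g = gt.build_glcm(quantized(img, 16), symmetric=True)
        sk = graycomatrix(
            img, distances=[1], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=16, symmetric=True, normed=False,
        )
        counts = sk[:, :, 0, :].sum(axis=2)
        np.testing.assert_allclose(g.probabilities, counts / counts.sum())

    def test_one_pixel_roi_is_degenerate(self):
        levels = np.full((3, 3), gt.QuantizedRoi.INVALID)
        levels[1, 1] = 0
        with pytest.raises(ValueError):
            gt.build_glcm(quantized(levels, 2))


def random_glcm(rng, n):
    P = rng.random((n, n))
    P[rng.random((n, n)) < 0.3] = 0.0
    if P.sum() == 0:
        P[0, 0] = 1.0
    P /= P.sum()
    return gt.GlcmMatrix(probabilities=P, n_levels=n, offsets_used=DEFAULT_OFFSETS,
                         pair_count=100)


class TestGlcmFeatures:
    def test_constant_image_fixed_points(self):
        P = np.zeros((8, 8))
        P[5, 5] = 1.0
        f = gt.glcm_features(
            gt.GlcmMatrix(probabilities=P, n_levels=8, offsets_used=DEFAULT_OFFSETS,
                          pair_count=10)
        )
        assert f.energy == 1.0 and f.contrast == 0.0
        assert f.entropy == 0.0 and f.homogeneity == 1.0
        assert f.variance_i == f.variance_j == 0.0
        assert f.cluster_shade == f.cluster_prominence == 0.0
        assert f.mean_i == f.mean_j == 5.0
        assert f.correlation == 0.0 and f.correlation_degenerate

    def test_uniform_2x2_closed_form(self):
        P = np.full((2, 2), 0.25)
        f = gt.glcm_features(
            gt.GlcmMatrix(probabilities=P, n_levels=2, offsets_used=DEFAULT_OFFSETS,
                          pair_count=4)
        )
        assert f.energy == pytest.approx(0.25)
        assert f.entropy == pytest.approx(np.log(4))
        assert f.contrast == pytest.approx(0.5)
        assert f.correlation == pytest.approx(0.0, abs=1e-15)

    def test_matches_naive_double_loop(self, rng):
        for n in (2, 5, 9):
            for _ in range(10):
                g = random_glcm(rng, n)
                f = gt.glcm_features(g)
                ref = naive_glcm_features(g.probabilities)
                for key, val in ref.items():
                    assert getattr(f, key) == pytest.approx(val, rel=1e-12, abs=1e-12), key

    def test_invariant_ranges_on_random_matrices(self, rng):
        for _ in range(200):
            f = gt.glcm_features(random_glcm(rng, int(rng.integers(2, 12))))
            n = 12
            assert 0 < f.energy <= 1
            assert 0 <= f.entropy <= 2 * np.log(n)
            assert 0 < f.homogeneity <= 1
            assert f.contrast >= 0 and f.cluster_prominence >= -1e-12
            assert abs(f.correlation) <= 1 + 1e-12

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            gt.GlcmMatrix(probabilities=np.full((2, 2), 0.3), n_levels=2,
                          offsets_used=DEFAULT_OFFSETS, pair_count=4)


class TestExtractFeatureVector:
    def test_sixteen_named_features_in_order(self, rng):
        adc = adc_of(rng.uniform(0.5e-3, 1.5e-3, (20, 20)))
        vec = gt.extract_feature_vector(adc, full_roi((20, 20)), age=40, gender="female")
        assert tuple(vec) == gt.FEATURE_NAMES
        assert vec["Patients' age"] == 40.0 and vec["Patients' gender"] == 0.0

    def test_symmetric_mode_equates_the_two_marginals(self, rng):
        adc = adc_of(rng.uniform(0.5e-3, 1.5e-3, (20, 20)))
        vec = gt.extract_feature_vector(adc, full_roi((20, 20)), age=30, gender="male",
                                        symmetric=True)
        assert vec["GLCM mean 1"] == pytest.approx(vec["GLCM mean 2"], rel=1e-12)
        assert vec["GLCM variance 1"] == pytest.approx(vec["GLCM variance 2"], rel=1e-12)

    def test_constant_roi_composition(self):
        vec = gt.extract_feature_vector(
            adc_of(np.full((10, 10), 0.9e-3)), full_roi((10, 10)), age=55, gender="male"
        )
        assert vec["Skewness"] == 0.0 and vec["Kurtosis"] == 0.0
        assert vec["Energy"] == 1.0 and vec["Contrast"] == 0.0

    def test_glcm_features_invariant_to_monotone_affine_adc_transform(self, rng):
        adc_vals = rng.uniform(0.5e-3, 1.5e-3, (18, 18))
        roi = full_roi((18, 18))
        v1 = gt.extract_feature_vector(adc_of(adc_vals), roi, age=1, gender=0)
        v2 = gt.extract_feature_vector(adc_of(2.0 * adc_vals + 1e-4), roi, age=1, gender=0)
        for name in ("Energy", "Entropy", "Contrast", "Homogeneity", "Correlation",
                     "Prominence", "Shade", "GLCM mean 1", "GLCM mean 2"):
            assert v1[name] == pytest.approx(v2[name], rel=1e-12)

    def test_unknown_gender_rejected(self):
        with pytest.raises(ValueError):
            gt.extract_feature_vector(adc_of(np.ones((5, 5))), full_roi((5, 5)),
                                      age=10, gender="other")
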