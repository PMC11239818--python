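"""Feature-extraction correctness: first-order statistics, quantization,
co-occurrence matrices and their 25 statistics, and the 310-feature contract."""

import numpy as np
import pytest

from deltarad.datatypes import MRIStudy, VOIMask
from deltarad.radiomics import (
    DIRECTIONS_2D,
    FIRST_ORDER_NAMES,
    GLCM_STATISTIC_NAMES,
    GLCMConfig,
    QuantizationParams,
    extract_feature_vector,
    first_order_features,
    glcm_features,
    glcm_matrix,
    glcm_statistics,
    quantize,
)

from oracles import brute_glcm, brute_glcm_statistics


class TestFirstOrder:
    def test_against_brute_force_on_1_to_100(self):
        values = np.arange(1, 101, dtype=float)
        f = first_order_features(values)
        assert f["firstorder_minimum"] == 1.0
        assert f["firstorder_maximum"] == 100.0
        assert f["firstorder_mean"] == pytest.approx(50.5)
        # linear interpolation between order statistics
        assert f["firstorder_p5"] == pytest.approx(5.95)
        assert f["firstorder_p1"] == pytest.approx(1.99)
        assert f["firstorder_stddev"] == pytest.approx(np.std(values, ddof=1))

    def test_constant_input_degenerates_cleanly(self):
        f = first_order_features(np.full(40, 7.0))
        for name in ("minimum", "maximum", "mean", "p1", "p5", "p95", "p99"):
            assert f[f"firstorder_{name}"] == 7.0
        assert f["firstorder_stddev"] == 0.0
        assert f["firstorder_skewness"] == 0.0
        assert f["firstorder_kurtosis"] == 0.0

    def test_count_and_empty_input(self):
        assert len(FIRST_ORDER_NAMES) == 10
        f = first_order_features(np.array([]))
        assert len(f) == 10 and all(np.isnan(v) for v in f.values())

    def test_shift_moves_location_not_shape(self, rng):
        v = rng.normal(size=200)
        base = first_order_features(v)
        shifted = first_order_features(v + 5.0)
        for name in ("minimum", "maximum", "mean", "p1", "p5", "p95", "p99"):
            assert shifted[f"firstorder_{name}"] == pytest.approx(base[f"firstorder_{name}"] + 5.0)
        for name in ("stddev", "skewness", "kurtosis"):
            assert shifted[f"firstorder_{name}"] == pytest.approx(base[f"firstorder_{name}"])


class TestQuantize:
    def test_identity_mapping_for_aligned_range(self):
        vol = np.arange(32, dtype=float).reshape(2, 4, 4)
        mask = np.ones_like(vol, dtype=bool)
        q = quantize(vol, mask, QuantizationParams(n_levels=32))
        assert np.array_equal(np.sort(np.unique(q)), np.arange(1, 33))
        assert q.ravel()[0] == 1 and q.ravel()[-1] == 32

    def test_constant_voi_single_level(self):
        vol = np.full((3, 3, 3), 2.5)
        mask = np.ones_like(vol, dtype=bool)
        q = quantize(vol, mask)
        assert set(np.unique(q[mask])) == {1}

    def test_levels_within_bounds(self, rng):
        vol = rng.normal(size=(6, 6, 3))
        mask = rng.uniform(size=vol.shape) > 0.4
        mask[0, 0, 0] = True
        q = quantize(vol, mask, QuantizationParams(n_levels=8))
        assert q[~mask].max(initial=0) == 0
        assert 1 <= q[mask].min() and q[mask].max() <= 8


class TestGLCMMatrix:
    def test_hand_enumerated_2x2_slice(self):
        # one axial slice [[1,1],[1,2]], offset (1,0): vertical pairs
        # (1,1) and (1,2); symmetric counts {(1,1):2, (1,2):1, (2,1):1}
        q = np.array([[1, 1], [1, 2]]).reshape(2, 2, 1)
        P = glcm_matrix(q, (1, 0), n_levels=2, symmetric=True)
        assert P[0, 0] == pytest.approx(0.5)
        assert P[0, 1] == pytest.approx(0.25)
        assert P[1, 0] == pytest.approx(0.25)
        assert P[1, 1] == 0.0

    def test_constant_voi_single_entry(self):
        q = np.ones((4, 4, 2), dtype=int)
        P = glcm_matrix(q, (1, 0), n_levels=4)
        assert P[0, 0] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_normalization_and_symmetry_random(self, rng):
        q = rng.integers(0, 5, size=(6, 6, 3))
        for offset in [(1, 0), (0, 2), (1, -1), (1, 1, 1)]:
            P = glcm_matrix(q, offset, n_levels=4, symmetric=True)
            if P is None:
                continue
            assert P.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(P, P.T)

    def test_no_valid_pairs_returns_none(self):
        q = np.zeros((3, 3, 2), dtype=int)
        q[0, 0, 0] = 1  # isolated voxel: no co-occurring neighbor
        assert glcm_matrix(q, (1, 0), n_levels=2) is None


class TestGLCMStatistics:
    def test_single_entry_matrix_limits(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        s = glcm_statistics(P)
        assert s["contrast"] == 0.0
        assert s["joint_energy"] == 1.0
        assert s["joint_entropy"] == 0.0
        assert s["maximum_probability"] == 1.0
        assert s["correlation"] == 1.0  # analytic limit for zero variance

    def test_hand_computed_contrast(self):
        q = np.array([[1, 1], [1, 2]]).reshape(2, 2, 1)
        P = glcm_matrix(q, (1, 0), n_levels=2)
        s = glcm_statistics(P)
        assert s["contrast"] == pytest.approx(0.5 * 0 + 0.5 * 1)
        assert s["dissimilarity"] == pytest.approx(0.5)

    def test_uniform_matrix_entropy(self):
        L = 8
        P = np.full((L, L), 1.0 / L**2)
        s = glcm_statistics(P)
        assert s["joint_entropy"] == pytest.approx(2 * np.log2(L))
        assert s["joint_energy"] == pytest.approx(1.0 / L**2)

    def test_missing_matrix_gives_all_nan(self):
        s = glcm_statistics(None)
        assert len(s) == 25 and all(np.isnan(v) for v in s.values())

    def test_matches_brute_force_on_random_arrays(self, rng):
        """Vectorized statistics equal explicit-loop enumeration to 1e-10."""
        for _ in range(3):
            q = rng.integers(0, 7, size=(6, 6, 3))
            for offset in [(1, 0, 0), (0, 1, 0), (2, 2, 0), (1, -1, 0)]:
                P = glcm_matrix(q, offset, n_levels=6)
                if P is None:
                    continue
                expected = brute_glcm_statistics(brute_glcm(q, offset, 6))
                got = glcm_statistics(P)
                for name in GLCM_STATISTIC_NAMES:
                    assert got[name] == pytest.approx(expected[name], abs=1e-10), name


def _study_from_volume(vol, spacing=(1.0, 1.0, 1.0)):
    return MRIStudy("P000", "BL", vol, vol.copy(), spacing)


class TestExtraction:
    def test_exactly_310_named_features(self, rng):
        vol = rng.normal(size=(12, 12, 6))
        mask = np.zeros_like(vol, dtype=bool)
        mask[3:9, 3:9, 1:5] = True
        fv = extract_feature_vector(_study_from_volume(vol), VOIMask("P000", "BL", mask), "DCE")
        assert len(fv) == 310
        n_fo = sum(1 for n in fv.values if n.startswith("firstorder_"))
        n_glcm = sum(1 for n in fv.values if n.startswith("glcm_"))
        assert (n_fo, n_glcm) == (10, 300)
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_determinism_and_translation_invariance(self, rng):
        vol = rng.normal(size=(14, 14, 6))
        mask = np.zeros_like(vol, dtype=bool)
        mask[2:8, 2:8, 1:4] = True
        fv1 = extract_feature_vector(_study_from_volume(vol), VOIMask("P000", "BL", mask), "DCE")
        fv2 = extract_feature_vector(_study_from_volume(vol), VOIMask("P000", "BL", mask), "DCE")
        assert fv1.values == fv2.values
        shifted_vol = np.roll(vol, (3, 2, 1), axis=(0, 1, 2))
        shifted_mask = np.roll(mask, (3, 2, 1), axis=(0, 1, 2))
        fv3 = extract_feature_vector(
            _study_from_volume(shifted_vol), VOIMask("P000", "BL", shifted_mask), "DCE"
        )
        for name in fv1.values:
            assert fv3.values[name] == pytest.approx(fv1.values[name], rel=1e-12), name

    def test_intensity_shift_leaves_glcm_invariant(self, rng):
        vol = rng.normal(size=(12, 12, 5))
        mask = np.zeros_like(vol, dtype=bool)
        mask[3:10, 3:10, 1:4] = True
        voi = VOIMask("P000", "BL", mask)
        base = glcm_features(vol, voi)
        shifted = glcm_features(vol + 100.0, voi)
        for name in base:
            assert shifted[name] == pytest.approx(base[name], rel=1e-9), name

    def test_empty_voi_yields_all_missing(self, rng):
        vol = rng.normal(size=(8, 8, 4))
        voi = VOIMask("P000", "BL", np.zeros_like(vol, dtype=bool), tumor_bed=True)
        fv = extract_feature_vector(_study_from_volume(vol), voi, "DWI")
        assert len(fv) == 310 and all(np.isnan(v) for v in fv.values.values())

    def test_contrast_rises_with_texture_heterogeneity(self, rng):
        """GLCM contrast (averaged over offsets) grows with texture s.d.

        Quantization is VOI-min-max relative, so the phantom pins the
        intensity range with two anchor voxels (0 and 100) and grows the
        texture standard deviation inside that fixed dynamic range.
        """
        from scipy import ndimage

        mask = np.zeros((16, 16, 6), dtype=bool)
        mask[3:13, 3:13, 1:5] = True
        voi = VOIMask("P000", "BL", mask)
        texture = ndimage.gaussian_filter(rng.normal(size=mask.shape), sigma=1.5)
        texture /= texture.std()
        contrasts = []
        for sd in np.linspace(1.0, 12.0, 10):
            vol = np.clip(50.0 + sd * texture, 0.0, 100.0)
            vol[3, 3, 1] = 0.0    # fixed range anchors
            vol[12, 12, 4] = 100.0
            feats = glcm_features(vol, voi)
            contrasts.append(np.mean([v for k, v in feats.items() if "_contrast_" in k]))
        assert np.all(np.diff(contrasts) > 0)

    def test_default_config_feature_count_identity(self):
        cfg = GLCMConfig()
        assert cfg.n_features == 300
        assert len(cfg.feature_names()) == 300
        assert len(DIRECTIONS_2D) == 4
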