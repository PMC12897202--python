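"""The 93-feature suite: hand-derived worked examples, brute-force oracle
equivalence, and structural invariants."""

import numpy as np
import pytest

from mitotexture.image import Image2D
from mitotexture.quantize import QuantizedROI, quantize_fixed_bin_count
from mitotexture.features import (FAMILIES, FEATURE_NAMES, FeatureConfig,
                                  extract_all, firstorder_features,
                                  glcm_features, glcm_matrix, gldm_features,
                                  gldm_matrix, glrlm_features, glrlm_matrix,
                                  glszm_features, ngtdm_features, ngtdm_matrix)
from oracles import o_all_features


def _q_identity(arr) -> QuantizedROI:
    """Treat an integer array as pre-assigned gray levels 1..Ng."""
    arr = np.asarray(arr, dtype=int)
    return QuantizedROI(arr, int(arr.max()), np.ones(arr.shape, dtype=bool), 1.0)


class TestFirstOrder:
    def test_tiny_worked_example(self):
        img = Image2D(np.array([[1, 2], [3, 4]], dtype=np.uint8))
        f = firstorder_features(img.astype_float(), _q_identity([[1, 2], [3, 4]]))
        assert f["Mean"] == 2.5
        assert f["Minimum"] == 1 and f["Maximum"] == 4
        assert f["Energy"] == 30
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(30 / 4))

    def test_constant_roi_zero_variance_convention(self):
        f = firstorder_features(np.full((3, 3), 7.0), _q_identity(np.ones((3, 3))))
        assert f["Variance"] == 0
        assert f["Skewness"] == 0 and f["Kurtosis"] == 0
        assert f["Uniformity"] == 1.0 and f["Entropy"] == pytest.approx(0, abs=1e-12)

    def test_population_moments_match_formula(self):
        x = np.array([1.0, 1.0, 1.0, 10.0]).reshape(2, 2)
        f = firstorder_features(x, _q_identity([[1, 1], [1, 2]]))
        mu = x.mean()
        m2 = ((x - mu) ** 2).mean()
        m3 = ((x - mu) ** 3).mean()
        m4 = ((x - mu) ** 4).mean()
        assert f["Skewness"] == pytest.approx(m3 / m2**1.5, rel=1e-12)
        assert f["Kurtosis"] == pytest.approx(m4 / m2**2, rel=1e-12)


class TestGLCM:
    def test_checkerboard_horizontal_cooccurrence(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 + 1
        counts = glcm_matrix(_q_identity(board))
        P = counts[0] / counts[0].sum()          # angle (0, 1)
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == 0 and P[1, 1] == 0

    def test_constant_roi_degenerate_matrix_and_conventions(self):
        q = _q_identity(np.ones((4, 4)))
        counts = glcm_matrix(q)
        for a in range(4):
            assert counts[a].sum() > 0
            assert (counts[a] / counts[a].sum())[0, 0] == 1.0
        f = glcm_features(q)
        assert f["Contrast"] == 0
        assert f["JointEntropy"] == pytest.approx(0, abs=1e-12)
        assert f["MaximumProbability"] == 1.0
        assert f["Correlation"] == 1.0

    def test_all_distinct_2x2_joint_entropy(self):
        # horizontal and vertical angles each see 2 pairs -> 4 equiprobable
        # symmetric entries -> 2 bits
        q = _q_identity([[1, 2], [3, 4]])
        counts = glcm_matrix(q)
        for a in (0, 2):                         # (0,1) and (1,0)
            P = counts[a] / counts[a].sum()
            ent = -np.sum(P[P > 0] * np.log2(P[P > 0]))
            assert ent == pytest.approx(2.0)

    def test_normalized_matrices_sum_to_one(self, rng):
        arr = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        q = quantize_fixed_bin_count(Image2D(arr), 5)
        counts = glcm_matrix(q)
        for a in range(4):
            np.testing.assert_allclose((counts[a] / counts[a].sum()).sum(), 1.0)


class TestGLRLM:
    def test_single_run_matrix(self):
        q = _q_identity([[1, 1, 1, 1]])
        P = glrlm_matrix(q, (0, 1))
        assert P[0, 3] == 1 and P.sum() == 1

    def test_horizontal_run_emphases_from_matrix(self):
        # one run of length 4: LRE = 16, SRE = 1/16, RunPercentage = 1/4
        P = glrlm_matrix(_q_identity([[1, 1, 1, 1]]), (0, 1))
        Nr = P.sum()
        j2 = (np.arange(1, P.shape[1] + 1) ** 2)[None, :]
        assert float((P * j2).sum() / Nr) == 16.0
        assert float((P / j2).sum() / Nr) == 0.0625
        assert Nr / 4 == 0.25

    def test_alternating_line_all_singleton_runs(self):
        f = glrlm_features(_q_identity([[1, 2, 1, 2]]))
        assert f["ShortRunEmphasis"] == 1.0
        assert f["LongRunEmphasis"] == 1.0
        assert f["RunPercentage"] == 1.0


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        f = glszm_features(_q_identity(np.ones((3, 3))))
        assert f["ZonePercentage"] == pytest.approx(1 / 9)
        assert f["LargeAreaEmphasis"] == 81.0

    def test_two_zone_worked_example(self):
        f = glszm_features(_q_identity([[1, 1, 2], [1, 2, 2]]))
        assert f["ZonePercentage"] == pytest.approx(1 / 3)
        assert f["SizeZoneNonUniformity"] == pytest.approx(2.0)

    def test_checkerboard_diagonal_connectivity(self):
        # under 8-connectivity each parity of a checkerboard is one zone:
        # 2 zones of size 8 -> SmallAreaEmphasis = (2/2)/8**2, ZP = 2/16
        board = np.indices((4, 4)).sum(axis=0) % 2 + 1
        f = glszm_features(_q_identity(board))
        assert f["SmallAreaEmphasis"] == pytest.approx(1 / 64)
        assert f["ZonePercentage"] == pytest.approx(1 / 8)

    def test_all_distinct_levels_all_singleton_zones(self):
        arr = np.arange(1, 17).reshape(4, 4)
        f = glszm_features(_q_identity(arr))
        assert f["SmallAreaEmphasis"] == 1.0
        assert f["ZonePercentage"] == 1.0


class TestNGTDM:
    def test_constant_roi_conventions(self):
        f = ngtdm_features(_q_identity(np.ones((4, 4))))
        assert f["Coarseness"] == 1.0e6
        assert f["Contrast"] == 0.0
        assert f["Complexity"] == 0.0

    def test_center_spot_s_values_by_hand(self):
        arr = np.ones((3, 3), dtype=int)
        arr[1, 1] = 2
        n, p, s = ngtdm_matrix(_q_identity(arr))
        # center: |2 - mean(eight 1s)| = 1; corners: |1 - (2+2)/3 ... | hand:
        # corner neighbors = {1,1,2} -> mean 4/3, diff 1/3 (x4 corners)
        # edge neighbors = {1,1,1,1,2} -> mean 6/5, diff 1/5 (x4 edges)
        assert s[1] == pytest.approx(1.0)
        assert s[0] == pytest.approx(4 * (1 / 3) + 4 * (1 / 5))
        assert n.tolist() == [8, 1]


class TestGLDM:
    def test_constant_roi_dependence_sizes(self):
        f = gldm_features(_q_identity(np.ones((3, 3))), alpha=0)
        # corners have 3 dependent neighbors (j=4), edges 5 (j=6), center 8 (j=9)
        assert f["LargeDependenceEmphasis"] == pytest.approx(289 / 9)

    def test_matrix_row_sums_equal_level_counts(self, rng):
        arr = rng.integers(0, 256, size=(7, 7)).astype(np.uint8)
        q = quantize_fixed_bin_count(Image2D(arr), 4)
        P = gldm_matrix(q, alpha=0)
        counts = np.bincount(q.levels.ravel(), minlength=q.Ng + 1)[1:]
        np.testing.assert_array_equal(P.sum(axis=1), counts)


class TestExtractAll:
    def test_census_is_93_with_family_split(self):
        assert len(FEATURE_NAMES) == 93
        assert {f: len(v) for f, v in FAMILIES.items()} == {
            "firstorder": 18, "glcm": 24, "gldm": 14,
            "glrlm": 16, "glszm": 16, "ngtdm": 5}

    def test_identical_rois_identical_vectors(self, rng):
        arr = rng.integers(0, 256, size=(69, 69)).astype(np.uint8)
        a = extract_all(Image2D(arr))
        b = extract_all(Image2D(arr.copy()))
        assert a.values == b.values

    def test_rotation_average_symmetry(self, rng):
        # the 4-direction angle set maps onto itself under a 90-degree
        # rotation, so direction-averaged GLCM/GLRLM features are invariant
        arr = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        a = extract_all(Image2D(arr))
        b = extract_all(Image2D(np.rot90(arr).copy()))
        for name in FEATURE_NAMES:
            if name.startswith(("glcm_", "glrlm_")):
                assert a.values[name] == pytest.approx(b.values[name], rel=1e-9), name

    def test_bounds_and_normalization_invariants(self, rng):
        for _ in range(10):
            arr = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
            v = extract_all(Image2D(arr)).values
            assert 0 < v["glrlm_ShortRunEmphasis"] <= 1
            assert 0 < v["glszm_SmallAreaEmphasis"] <= 1
            assert 0 < v["gldm_SmallDependenceEmphasis"] <= 1
            assert 0 < v["glrlm_RunPercentage"] <= 1
            assert 0 < v["glszm_ZonePercentage"] <= 1
            assert 0 <= v["glcm_Imc2"] < 1
            assert 0 < v["glcm_MaximumProbability"] <= 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(12))
    def test_all_families_match_bruteforce(self, trial):
        rng = np.random.default_rng(5000 + trial)
        h, w = rng.integers(4, 17, size=2)
        ng = int(rng.integers(2, 9))
        arr = rng.integers(0, 256, size=(h, w)).astype(np.uint8)
        img = Image2D(arr)
        cfg = FeatureConfig(quantization="fixed_count", n_bins=ng)
        q = cfg.quantize(img)
        got = extract_all(img, cfg).values
        ref = o_all_features(arr.astype(float), np.asarray(q.levels), q.Ng,
                             np.asarray(q.mask))
        for name in FEATURE_NAMES:
            assert got[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name
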