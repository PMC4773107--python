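"""Quantization, texture matrices, and the 12-feature set."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import random_masked_grid

from pettex import (
    PetVolume,
    build_glcm,
    build_glszm,
    build_ngtdm,
    extract_all,
    glcm_features,
    glszm_features,
    ngtdm_features,
    quantize,
    quantize_voi,
    suv_entropy,
)
from pettex.segmentation import SegmentationResult
from pettex.texture import COARSENESS_CAP, NGTDM_EPS, FEATURE_NAMES, GlszmMatrix


def _q_from(levels, mask, n_bins):
    """QuantizedVoi carrying externally chosen levels (bypassing min-max)."""
    from pettex.texture import QuantizedVoi

    counts = np.bincount(levels[mask], minlength=n_bins + 1)[1:]
    n = int(mask.sum())
    return QuantizedVoi(levels=levels, mask=mask, n_bins=n_bins,
                        bin_edges=np.arange(n_bins + 1, dtype=float),
                        counts=counts, p=counts / n, n_voxels=n)


def _seg_for(vol, mask):
    vals = vol.values[mask]
    mtv = int(mask.sum()) * vol.voxel_volume_cm3
    return SegmentationResult(method="test", threshold=float(vals.min()),
                              mask=mask, suvmax=float(vals.max()),
                              suvmean=float(vals.mean()), mtv_cm3=mtv,
                              tlg=float(vals.mean()) * mtv)


class TestQuantize:
    def test_boundary_mapping(self):
        assert quantize([2.0, 4.0], 64).tolist() == [1, 64]

    def test_constant_input_maps_to_level_one(self):
        assert np.all(quantize(np.full(10, 3.3), 64) == 1)

    def test_uniform_values_fill_bins_evenly(self):
        rng = np.random.default_rng(0)
        lev = quantize(rng.random(1000), 64)
        p = np.bincount(lev, minlength=65)[1:] / 1000
        assert np.abs(p - 1 / 64).max() < 0.05

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        vals = np.zeros((6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.7
        vals[mask] = rng.random(int(mask.sum())) * 10
        q = quantize_voi(vals, mask, 64)
        assert q.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert q.levels[mask].min() >= 1 and q.levels[mask].max() <= 64


class TestHistogramEntropy:
    def test_two_equal_bins(self):
        vals = np.zeros((8, 8, 8))
        mask = np.zeros_like(vals, dtype=bool)
        mask[0, 0, :8] = True
        vals[0, 0, :4] = 1.0
        assert suv_entropy(quantize_voi(vals, mask, 64)) == pytest.approx(1.0)

    def test_matches_direct_loop(self):
        rng = np.random.default_rng(2)
        vals = rng.random((6, 6, 6)) * 5
        mask = rng.random((6, 6, 6)) < 0.8
        q = quantize_voi(vals, mask, 64)
        expected = oracles.histogram_entropy(list(q.levels[mask]), 64)
        assert suv_entropy(q) == pytest.approx(expected, abs=1e-12)


class TestGlcm:
    def test_constant_cube(self):
        levels = np.zeros((4, 4, 4), dtype=np.int64)
        mask = np.zeros_like(levels, dtype=bool)
        mask[:2, :2, :2] = True
        levels[mask] = 1
        m = build_glcm(_q_from(levels, mask, 4))
        assert m.P[0, 0] == pytest.approx(1.0)
        assert m.P.sum() == pytest.approx(1.0)

    def test_two_adjacent_voxels_symmetric(self):
        levels = np.zeros((8, 8, 8), dtype=np.int64)
        mask = np.zeros_like(levels, dtype=bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True
        levels[0, 0, 0], levels[0, 0, 1] = 1, 2
        m = build_glcm(_q_from(levels, mask, 2))
        assert m.P[0, 1] == pytest.approx(0.5)
        assert m.P[1, 0] == pytest.approx(0.5)

    def test_isolated_voxels_error(self):
        levels = np.zeros((8, 8, 8), dtype=np.int64)
        mask = np.zeros_like(levels, dtype=bool)
        mask[0, 0, 0] = mask[4, 4, 4] = True
        levels[mask] = 1
        with pytest.raises(ValueError, match="co-occurrence"):
            build_glcm(_q_from(levels, mask, 2))

    def test_feature_closed_forms(self):
        P = np.zeros((2, 2))
        P[0, 1] = P[1, 0] = 0.5
        from pettex.texture import GlcmMatrix

        f = glcm_features(GlcmMatrix(P=P, n_bins=2))
        assert (f.entropy, f.uniformity, f.dissimilarity, f.homogeneity) == \
            pytest.approx((1.0, 0.5, 1.0, 0.5))


class TestNgtdm:
    def test_constant_voi_zero_differences(self):
        levels = np.ones((4, 4, 4), dtype=np.int64)
        mask = np.ones_like(levels, dtype=bool)
        t = build_ngtdm(_q_from(levels, mask, 2))
        assert np.all(t.s == 0)

    def test_three_voxel_line_hand_case(self):
        # line of levels (1, 2, 1): the center sees mean neighbor level 1,
        # contributing |2 - 1| = 1 to s(2)
        levels = np.zeros((8, 8, 8), dtype=np.int64)
        mask = np.zeros_like(levels, dtype=bool)
        mask[0, 0, :3] = True
        levels[0, 0, :3] = [1, 2, 1]
        t = build_ngtdm(_q_from(levels, mask, 2))
        assert t.s[1] == pytest.approx(1.0)
        # each end voxel's only in-mask neighbor is the center (level 2)
        assert t.s[0] == pytest.approx(abs(1 - 2) + abs(1 - 2))

    def test_constant_voi_feature_values(self):
        levels = np.ones((4, 4, 4), dtype=np.int64)
        mask = np.ones_like(levels, dtype=bool)
        f = ngtdm_features(build_ngtdm(_q_from(levels, mask, 2)))
        assert f.coarseness == pytest.approx(COARSENESS_CAP)
        assert (f.busyness, f.contrast, f.complexity) == (0.0, 0.0, 0.0)

    def test_doubling_s_halves_coarseness(self):
        rng = np.random.default_rng(3)
        levels, mask = random_masked_grid(rng)
        t = build_ngtdm(_q_from(levels, mask, 6))
        import dataclasses

        t2 = dataclasses.replace(t, s=2 * t.s)
        c1 = ngtdm_features(t).coarseness
        c2 = ngtdm_features(t2).coarseness
        psum = float((t.p * t.s).sum())
        assert c2 == pytest.approx(1.0 / (NGTDM_EPS + 2 * psum))
        assert c1 > c2


class TestGlszm:
    def test_constant_connected_voi_single_zone(self):
        levels = np.zeros((5, 5, 5), dtype=np.int64)
        mask = np.zeros_like(levels, dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        levels[mask] = 1
        z = build_glszm(_q_from(levels, mask, 2))
        assert z.n_z == 1
        assert z.Z[0, 26] == 1  # one zone of size 27

    def test_corner_touching_voxels_one_zone(self):
        levels = np.zeros((8, 8, 8), dtype=np.int64)
        mask = np.zeros_like(levels, dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        levels[mask] = 1
        z = build_glszm(_q_from(levels, mask, 2))
        assert z.n_z == 1

    def test_feature_closed_forms(self):
        # one zone of level 3, size 4
        Z = np.zeros((4, 4), dtype=np.int64)
        Z[2, 3] = 1
        f = glszm_features(GlszmMatrix(Z=Z, n_bins=4, n_z=1, n=4))
        assert (f.glnu, f.zsnu) == (1.0, 1.0)
        assert f.hglze == pytest.approx(3**2 * 4**2)

    def test_two_zones_same_level(self):
        # sizes 1 and 2 at one level: glnu = 2^2/2 = 2, zsnu = (1+1)/2 = 1
        Z = np.zeros((3, 2), dtype=np.int64)
        Z[0, 0] = Z[0, 1] = 1
        f = glszm_features(GlszmMatrix(Z=Z, n_bins=3, n_z=2, n=3))
        assert (f.glnu, f.zsnu) == (2.0, 1.0)

    def test_hglze_grey_level_only_option(self):
        Z = np.zeros((4, 4), dtype=np.int64)
        Z[2, 3] = 1
        f = glszm_features(GlszmMatrix(Z=Z, n_bins=4, n_z=1, n=4), hglze_mode="i2")
        assert f.hglze == pytest.approx(9.0)


class TestRandomGridOracles:
    """Brute-force enumeration agreement on random masked grids (a smaller
    replica of the acceptance-scale suite, kept here per matrix family)."""

    @pytest.mark.parametrize("seed", range(10))
    def test_all_matrices_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        levels, mask = random_masked_grid(rng)
        q = _q_from(levels, mask, 6)

        counts = oracles.glcm_counts(levels, mask, 6)
        if counts.sum() > 0:
            m = build_glcm(q)
            np.testing.assert_allclose(m.P, counts / counts.sum(), atol=1e-12)
            f = glcm_features(m)
            np.testing.assert_allclose(
                [f.entropy, f.uniformity, f.dissimilarity, f.homogeneity],
                oracles.glcm_feature_tuple(m.P), rtol=1e-10)

        s, cnt, n = oracles.ngtdm_table(levels, mask, 6)
        t = build_ngtdm(q)
        np.testing.assert_allclose(t.s, s, atol=1e-10)
        assert t.n == n
        f = ngtdm_features(t)
        np.testing.assert_allclose(
            [f.coarseness, f.busyness, f.contrast, f.complexity],
            oracles.ngtdm_feature_tuple(t.s, t.p, t.n_gp, t.n), rtol=1e-10)

        zones = oracles.glszm_zones(levels, mask)
        z = build_glszm(q)
        got = sorted(
            (i + 1, j + 1)
            for i, j in zip(*np.nonzero(z.Z))
            for _ in range(z.Z[i, j])
        )
        assert got == zones
        f = glszm_features(z)
        np.testing.assert_allclose(
            [f.glnu, f.zsnu, f.hglze],
            oracles.glszm_feature_tuple(zones, z.n_z), rtol=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_normalization_invariants(self, seed):
        rng = np.random.default_rng(seed)
        levels, mask = random_masked_grid(rng, shape=(4, 4, 4))
        q = _q_from(levels, mask, 6)
        z = build_glszm(q)
        j = np.arange(1, z.Z.shape[1] + 1)
        assert (z.Z * j).sum() == q.n_voxels  # zone mass conservation
        assert z.n_z == z.Z.sum() >= 1
        try:
            m = build_glcm(q)
        except ValueError:
            return
        assert m.P.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(m.P, m.P.T, atol=0)


class TestExtractAll:
    def test_constant_lesion_closed_form_vector(self):
        vals = np.zeros((8, 8, 8))
        vals[2:5, 2:5, 2:5] = 4.0
        mask = vals > 0
        vol = PetVolume(values=vals, spacing=(4.46, 5.46, 3.27))
        with pytest.warns(UserWarning, match="degenerate"):
            f = extract_all(vol, _seg_for(vol, mask))
        assert [getattr(f, n) for n in FEATURE_NAMES] == [
            0.0, 0.0, 1.0, 0.0, 1.0, COARSENESS_CAP, 0.0, 0.0, 0.0,
            1.0, 1.0, 27.0**2,
        ]

    def test_affine_rescale_leaves_features_bit_identical(self, small_phantom):
        vol, seed, bg = small_phantom
        from pettex import adaptive_threshold_segment, measure_background

        seg = adaptive_threshold_segment(vol, seed, measure_background(vol, bg))
        f1 = extract_all(vol, seg)
        f2 = extract_all(vol.with_values(2.0 * vol.values + 3.0), seg)
        assert f1.as_dict() == f2.as_dict()

    def test_entropy_bounds(self, small_phantom):
        vol, seed, bg = small_phantom
        from pettex import adaptive_threshold_segment, measure_background

        seg = adaptive_threshold_segment(vol, seed, measure_background(vol, bg))
        f = extract_all(vol, seg)
        assert 0 <= f.suv_entropy <= np.log2(64)
        assert 0 <= f.glcm_entropy <= 2 * np.log2(64)
        assert 0 < f.uniformity <= 1
        assert 0 < f.homogeneity <= 1

    def test_end_to_end_equals_per_matrix_path(self, small_phantom):
        vol, seed, bg = small_phantom
        from pettex import adaptive_threshold_segment, measure_background

        seg = adaptive_threshold_segment(vol, seed, measure_background(vol, bg))
        f = extract_all(vol, seg)
        q = quantize_voi(vol.values, seg.mask, 64)
        g = glcm_features(build_glcm(q))
        ng = ngtdm_features(build_ngtdm(q))
        gz = glszm_features(build_glszm(q))
        assert f.suv_entropy == suv_entropy(q)
        assert (f.glcm_entropy, f.uniformity) == (g.entropy, g.uniformity)
        assert (f.coarseness, f.busyness, f.contrast, f.complexity) == (
            ng.coarseness, ng.busyness, ng.contrast, ng.complexity)
        assert (f.glnu, f.zsnu, f.hglze) == (gz.glnu, gz.zsnu, gz.hglze)

    def test_heterogeneity_raises_entropy(self):
        """More within-tumor heterogeneity should raise histogram entropy."""
        from pettex import (PhantomConfig, adaptive_threshold_segment,
                            generate_phantom, measure_background)

        means = []
        for amp in (0.5, 3.0):
            es = []
            for seed in range(4):
                cfg = PhantomConfig(heterogeneity_amplitude=amp, seed=seed)
                vol, sm, bg = generate_phantom(cfg)
                seg = adaptive_threshold_segment(vol, sm,
                                                 measure_background(vol, bg))
                es.append(extract_all(vol, seg).suv_entropy)
            means.append(np.mean(es))
        assert means[0] < means[1]
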