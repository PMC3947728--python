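"""Tests for the fusion pipelines: decomposition conservation, saliency
behavior, weight-map semantics, refinement and reconstruction identities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from guidedfusion import (
    FusionConfig,
    LmmseParams,
    TwoScaleDecomposition,
    WeightLevelTable,
    WeightMapSet,
    binary_weight_maps,
    fuse,
    laplacian_magnitude,
    multilevel_weight_maps,
    normalize_saliency_pair,
    normalize_weight_set,
    reconstruct,
    refine_weights,
    saliency_gff,
    saliency_lmmse,
    two_scale_decompose,
)
from guidedfusion.phantom import generate_phantom_pair


class TestTwoScaleDecompose:
    def test_constant(self, default_cfg):
        d = two_scale_decompose(np.full((40, 40), 0.7), default_cfg)
        assert np.allclose(d.base, 0.7) and np.allclose(d.detail, 0.0)

    @given(arrays(np.float64, (24, 24), elements=st.floats(0, 1, width=32)))
    @settings(max_examples=25, deadline=None)
    def test_conservation(self, img):
        d = two_scale_decompose(img, FusionConfig(avg_size=7))
        assert np.abs(d.base + d.detail - img).max() <= 1e-12

    def test_impulse_detail_value(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        d = two_scale_decompose(img, FusionConfig(avg_size=3))
        assert d.detail[4, 4] == pytest.approx(1.0 - 1.0 / 9.0)


class TestSaliency:
    def test_constant_zero(self, default_cfg):
        assert np.allclose(saliency_gff(np.full((32, 32), 0.5), default_cfg), 0.0)

    def test_step_edge_peak_at_edge(self, default_cfg):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        s = saliency_gff(img, default_cfg)
        col_profile = s.mean(axis=0)
        peak = np.argmax(col_profile)
        assert peak in (31, 32)
        assert col_profile[0] < col_profile[peak] and col_profile[-1] < col_profile[peak]

    def test_gff_saliency_homogeneous(self, rng, default_cfg):
        img = rng.random((32, 32))
        s1 = saliency_gff(img, default_cfg)
        s2 = saliency_gff(3.0 * img, default_cfg)
        assert np.allclose(s2, 3.0 * s1, rtol=1e-9, atol=1e-12)

    def test_lmmse_sigma_zero_is_laplacian_magnitude(self, rng):
        img = rng.random((32, 32))
        cfg = FusionConfig(lmmse=LmmseParams(window=5, sigma_n=0.0))
        assert np.array_equal(saliency_lmmse(img, cfg), laplacian_magnitude(img))

    def test_lmmse_saliency_more_noise_robust_than_gff(self):
        pair = generate_phantom_pair(size=128, seed=7, sigma=0.1)
        cfg_noisy = FusionConfig(lmmse=LmmseParams(window=7, sigma_n=0.1))
        cfg_clean = FusionConfig(lmmse=LmmseParams(window=7, sigma_n=0.0))
        d_gff = np.abs(
            saliency_gff(pair.mr_noisy, cfg_noisy) - saliency_gff(pair.mr_clean, cfg_noisy)
        ).mean()
        d_lmmse = np.abs(
            saliency_lmmse(pair.mr_noisy, cfg_noisy) - saliency_lmmse(pair.mr_clean, cfg_clean)
        ).mean()
        assert d_lmmse < d_gff


class TestNormalizeSaliencyPair:
    def test_joint_scaling_preserves_order(self, rng):
        s2 = rng.random((10, 10))
        s1 = 2.0 * s2  # joint max 2 * max(s2)
        n1, n2 = normalize_saliency_pair(s1, s2)
        assert max(n1.max(), n2.max()) == pytest.approx(1.0)
        assert np.all((n1 >= n2) == (s1 >= s2))

    def test_all_zero_guard(self):
        n1, n2 = normalize_saliency_pair(np.zeros((5, 5)), np.zeros((5, 5)))
        assert np.all(n1 == 0) and np.all(n2 == 0)

    def test_scale_invariant(self, rng):
        s1, s2 = rng.random((8, 8)), rng.random((8, 8))
        a1, a2 = normalize_saliency_pair(s1, s2)
        b1, b2 = normalize_saliency_pair(5.0 * s1, 5.0 * s2)
        assert np.allclose(a1, b1, atol=1e-12) and np.allclose(a2, b2, atol=1e-12)


class TestBinaryWeightMaps:
    def test_strict_winner_and_tie(self):
        s1 = np.array([[0.5, 0.3]])
        s2 = np.array([[0.3, 0.3]])
        p1, p2 = binary_weight_maps(s1, s2)
        assert np.array_equal(p1, [[1.0, 1.0]])  # tie goes to the first image
        assert np.array_equal(p2, [[0.0, 0.0]])

    def test_exhaustive_2x2_against_pixel_comparison(self):
        values = [0.0, 0.5, 1.0]
        for flat1 in itertools.product(values, repeat=4):
            for flat2 in itertools.product(values, repeat=4):
                s1 = np.array(flat1).reshape(2, 2)
                s2 = np.array(flat2).reshape(2, 2)
                p1, p2 = binary_weight_maps(s1, s2)
                for idx in np.ndindex(2, 2):
                    expected = 1.0 if s1[idx] >= s2[idx] else 0.0
                    assert p1[idx] == expected and p2[idx] == 1.0 - expected


class TestMultilevelWeightMaps:
    @pytest.mark.parametrize(
        "delta,level",
        [(0.35, 1.0), (0.30, 1.0), (0.27, 0.8), (0.22, 0.7), (0.17, 0.6), (0.10, 0.0)],
    )
    def test_levels_where_a_wins(self, delta, level):
        s1 = np.array([[0.5 + delta, 0.5]])
        s2 = np.array([[0.5, 0.5]])
        p1, p2 = multilevel_weight_maps(s1, s2, WeightLevelTable())
        assert p1[0, 0] == pytest.approx(level)
        assert p2[0, 0] == 0.0

    def test_level_where_b_wins(self):
        s1 = np.array([[0.5]])
        s2 = np.array([[0.72]])
        p1, p2 = multilevel_weight_maps(s1, s2, WeightLevelTable())
        assert p2[0, 0] == pytest.approx(0.7)
        assert p1[0, 0] == 0.0

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            WeightLevelTable(levels=((0.15, 0.6), (0.30, 1.0)))
        with pytest.raises(ValueError):
            WeightLevelTable(levels=((0.30, 0.6), (0.15, 1.0)))


class TestRefineAndNormalize:
    def test_all_on_first_image(self, phantom, default_cfg):
        shape = phantom.ct.shape
        W = refine_weights(
            np.ones(shape), np.zeros(shape), phantom.mr_clean, phantom.ct, default_cfg
        )
        assert np.allclose(W.base_A, 1.0, atol=1e-9) and np.allclose(W.base_B, 0.0, atol=1e-9)

    def test_symmetric_half_weights(self, phantom, default_cfg):
        shape = phantom.ct.shape
        W = refine_weights(
            np.full(shape, 0.5), np.full(shape, 0.5), phantom.mr_clean, phantom.ct, default_cfg
        )
        for m in (W.base_A, W.base_B, W.detail_A, W.detail_B):
            assert np.allclose(m, 0.5, atol=1e-9)

    def test_refinement_smooths(self, rng, phantom, default_cfg):
        p1 = (rng.random(phantom.ct.shape) > 0.5).astype(float)
        W = refine_weights(p1, 1.0 - p1, phantom.mr_clean, phantom.ct, default_cfg)

        def total_variation(x):
            return float(np.abs(np.diff(x, axis=0)).sum() + np.abs(np.diff(x, axis=1)).sum())

        assert total_variation(W.base_A) <= total_variation(p1)

    def test_normalize_pixel_cases(self):
        raw = WeightMapSet(
            base_A=np.array([[0.2, 0.0]]),
            base_B=np.array([[0.6, 0.0]]),
            detail_A=np.array([[0.5, 1.0]]),
            detail_B=np.array([[0.5, 0.0]]),
        )
        W = normalize_weight_set(raw)
        assert W.base_A[0, 0] == pytest.approx(0.25)
        assert W.base_B[0, 0] == pytest.approx(0.75)
        assert W.base_A[0, 1] == pytest.approx(0.5)  # both-zero fallback
        assert W.base_B[0, 1] == pytest.approx(0.5)

    @given(
        arrays(np.float64, (6, 6), elements=st.floats(-0.5, 1.5, width=32)),
        arrays(np.float64, (6, 6), elements=st.floats(-0.5, 1.5, width=32)),
    )
    @settings(max_examples=25, deadline=None)
    def test_normalized_pairs_sum_to_one(self, wa, wb):
        W = normalize_weight_set(WeightMapSet(base_A=wa, base_B=wb, detail_A=wb, detail_B=wa))
        assert np.abs(W.base_A + W.base_B - 1.0).max() <= 1e-9
        assert np.abs(W.detail_A + W.detail_B - 1.0).max() <= 1e-9
        for m in (W.base_A, W.base_B, W.detail_A, W.detail_B):
            assert m.min() >= 0.0 and m.max() <= 1.0


class TestReconstruct:
    def _uniform_weights(self, shape):
        half = np.full(shape, 0.5)
        return WeightMapSet(base_A=half, base_B=half, detail_A=half, detail_B=half)

    def test_identical_sources_reproduced(self, rng, default_cfg):
        img = rng.random((32, 32))
        d = two_scale_decompose(img, default_cfg)
        out = reconstruct(self._uniform_weights(img.shape), d, d)
        assert np.abs(out - img).max() <= 1e-12

    def test_all_weight_on_a(self, rng, default_cfg):
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        da = two_scale_decompose(a, default_cfg)
        db = two_scale_decompose(b, default_cfg)
        ones, zeros = np.ones(a.shape), np.zeros(a.shape)
        W = WeightMapSet(base_A=ones, base_B=zeros, detail_A=ones, detail_B=zeros)
        assert np.abs(reconstruct(W, da, db) - a).max() <= 1e-12

    def test_hand_computed_2x2(self):
        da = TwoScaleDecomposition(
            base=np.array([[0.2, 0.4], [0.6, 0.8]]), detail=np.array([[0.1, -0.1], [0.0, 0.2]])
        )
        db = TwoScaleDecomposition(
            base=np.array([[0.5, 0.5], [0.5, 0.5]]), detail=np.array([[-0.2, 0.1], [0.3, -0.1]])
        )
        wa = np.array([[1.0, 0.5], [0.25, 0.0]])
        W = WeightMapSet(base_A=wa, base_B=1 - wa, detail_A=wa, detail_B=1 - wa)
        expected = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                expected[i, j] = (
                    wa[i, j] * da.base[i, j]
                    + (1 - wa[i, j]) * db.base[i, j]
                    + wa[i, j] * da.detail[i, j]
                    + (1 - wa[i, j]) * db.detail[i, j]
                )
        assert np.allclose(reconstruct(W, da, db), np.clip(expected, 0, 1), atol=1e-12)


class TestFuse:
    @pytest.mark.parametrize("scheme", ["gff", "improved"])
    def test_identical_inputs_identity(self, phantom, scheme):
        A = phantom.mr_clean
        out = fuse(A, A, FusionConfig(scheme=scheme))
        assert np.abs(out - A).max() <= 1e-9

    @pytest.mark.parametrize("scheme", ["gff", "improved"])
    def test_complementary_halves_recovered(self, scheme):
        truth = generate_phantom_pair(size=128, seed=11, sigma=0.0).mr_clean
        A = truth.copy()
        A[:, 64:] = 0.3
        B = truth.copy()
        B[:, :64] = 0.3
        F = fuse(A, B, FusionConfig(scheme=scheme))
        err_f = np.abs(F - truth).mean()
        assert err_f <= np.abs(A - truth).mean()
        assert err_f <= np.abs(B - truth).mean()

    def test_swap_symmetry_without_ties(self, rng):
        A = rng.random((64, 64))
        B = rng.random((64, 64))
        cfg = FusionConfig(scheme="gff")
        F1 = fuse(A, B, cfg)
        F2 = fuse(B, A, cfg)
        assert np.abs(F1 - F2).max() <= 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros((32, 32)), np.zeros((32, 33)), FusionConfig())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.full((32, 32), 1.5), np.zeros((32, 32)), FusionConfig())

    def test_output_in_unit_range(self, phantom):
        F = fuse(phantom.mr_noisy, phantom.ct, FusionConfig(scheme="improved"))
        assert F.min() >= 0.0 and F.max() <= 1.0
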