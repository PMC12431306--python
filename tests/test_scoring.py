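"""Anomaly-map arithmetic, fusion, image scoring, overlay, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tabanom.scoring import (ScoreWeights, cosine_map, euclidean_map,
                             fit_fusion_params, fuse_maps, image_score,
                             pyramid_maps, render_overlay, scale_map,
                             score_pair)


class TestEuclidean:
    def test_identical_features_zero(self, rng):
        F = rng.normal(size=(4, 8, 8))
        np.testing.assert_array_equal(euclidean_map(F, F), np.zeros((8, 8)))

    def test_hand_value(self):
        F = np.array([[[1.0]], [[2.0]]])
        Fh = np.array([[[1.0]], [[0.0]]])
        np.testing.assert_allclose(euclidean_map(F, Fh), [[2.0]])

    def test_symmetry_and_shape_guard(self, rng):
        F, Fh = rng.normal(size=(3, 5, 5)), rng.normal(size=(3, 5, 5))
        np.testing.assert_array_equal(euclidean_map(F, Fh), euclidean_map(Fh, F))
        with pytest.raises(ValueError):
            euclidean_map(F, rng.normal(size=(3, 4, 5)))


class TestCosine:
    def test_parallel_zero_orthogonal_one(self):
        F = np.array([[[1.0]], [[0.0]]])
        np.testing.assert_allclose(cosine_map(F, 2 * F), [[0.0]], atol=1e-7)
        Fh = np.array([[[0.0]], [[1.0]]])
        np.testing.assert_allclose(cosine_map(F, Fh), [[1.0]], atol=1e-7)

    def test_hand_value(self):
        F = np.array([[[1.0]], [[0.0]]])
        Fh = np.array([[[1.0]], [[1.0]]])
        np.testing.assert_allclose(cosine_map(F, Fh), [[1 - np.sqrt(2) / 2]],
                                   atol=1e-6)
        np.testing.assert_allclose(cosine_map(F, Fh), [[0.29289]], atol=1e-5)

    def test_zero_vectors_stable(self):
        z = np.zeros((3, 4, 4))
        out = cosine_map(z, z)
        assert np.all(np.isfinite(out))


class TestScaleMap:
    def test_lambda_endpoints(self, rng):
        dE, dC = rng.random((6, 6)), rng.random((6, 6))
        np.testing.assert_array_equal(scale_map(dE, dC, 1.0), dE)
        np.testing.assert_array_equal(scale_map(dE, dC, 0.0), dC)

    def test_default_lambda_hand_value(self):
        out = scale_map(np.array([[2.0]]), np.array([[0.29289]]), 0.85)
        np.testing.assert_allclose(out, [[1.7439335]], atol=1e-5)

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            scale_map(np.ones((2, 2)), np.ones((2, 2)), 1.2)


class TestFuse:
    def test_single_map_identity(self):
        m = np.random.default_rng(0).random((8, 8))
        w = ScoreWeights(lam=0.5, omega=[1.0], gamma=(1,))
        np.testing.assert_allclose(fuse_maps([m], w, shape=(8, 8)), m)

    def test_two_constant_maps(self):
        maps = [np.full((4, 4), 2.0), np.full((2, 2), 4.0)]
        w = ScoreWeights(lam=0.5, omega=[0.5, 0.5], gamma=(1, 2))
        np.testing.assert_allclose(fuse_maps(maps, w, shape=(4, 4)),
                                   np.full((4, 4), 3.0))

    def test_global_level_broadcasts(self):
        maps = [np.full((4, 4), 1.0), np.array([[5.0]])]
        w = ScoreWeights(lam=0.5, omega=[0.5, 0.5], gamma=(1, 0))
        np.testing.assert_allclose(fuse_maps(maps, w, shape=(4, 4)),
                                   np.full((4, 4), 3.0))

    def test_omega_validation(self):
        with pytest.raises(ValueError):
            ScoreWeights(omega=[0.5, 0.6])
        with pytest.raises(ValueError):
            ScoreWeights(omega=[-0.5, 1.5])

    def test_permutation_invariance(self, rng):
        maps = [rng.random((16, 16)), rng.random((8, 8)), rng.random((4, 4))]
        w = ScoreWeights(lam=0.5, omega=[0.2, 0.3, 0.5], gamma=(4, 8, 16))
        S1 = fuse_maps(maps, w, shape=(64, 64))
        perm = [2, 0, 1]
        w2 = ScoreWeights(lam=0.5, omega=np.array(w.omega)[perm],
                          gamma=tuple(np.array(w.gamma)[perm]))
        S2 = fuse_maps([maps[i] for i in perm], w2, shape=(64, 64))
        np.testing.assert_allclose(S1, S2)


class TestImageScore:
    def test_zero_field(self):
        assert image_score(np.zeros((16, 16)), sigma=2.0) == 0.0

    def test_bump_monotonicity(self, rng):
        S = rng.random((16, 16))
        S2 = S.copy()
        S2[8, 8] += 1.0
        assert image_score(S2, 1.5) >= image_score(S, 1.5)

    def test_unit_spike_gives_kernel_center_weight(self):
        """Peak response to a delta equals the squared 1-D center weight."""
        sigma = 0.5   # scipy radius = round(4*sigma) = 2 -> 5x5 kernel
        i = np.arange(-2, 3)
        g = np.exp(-0.5 * (i / sigma) ** 2)
        g /= g.sum()
        k = g[2] ** 2
        S = np.zeros((11, 11))
        S[5, 5] = 1.0
        np.testing.assert_allclose(image_score(S, sigma), k, rtol=1e-6)


class TestOverlay:
    def test_constant_field_rule(self, rng):
        from tabanom.scoring import _colormap
        x = rng.random((8, 8, 3))
        out = render_overlay(np.full((8, 8), 3.3), x)
        expect = np.clip(0.6 * _colormap(np.zeros((8, 8))) + 0.4 * x, 0, 1)
        np.testing.assert_allclose(out, expect)

    def test_blend_weights_and_range(self, rng):
        S = rng.random((8, 8))
        x = rng.random((8, 8, 3))
        out = render_overlay(S, x)
        assert out.shape == (8, 8, 3)
        assert out.min() >= 0 and out.max() <= 1
        hot = np.unravel_index(np.argmax(S), S.shape)
        expect_hot = 0.6 * np.array([0.5, 0.0, 0.0]) + 0.4 * x[hot]
        np.testing.assert_allclose(out[hot], np.clip(expect_hot, 0, 1), atol=1e-7)


class TestIdenticalPyramids:
    def test_all_maps_and_fused_zero(self, rng):
        pyr = [rng.normal(size=(8, 16, 16)), rng.normal(size=(16, 8, 8)),
               rng.normal(size=(32, 4, 4)), rng.normal(size=(64, 1, 1))]
        am = score_pair(pyr, [p.copy() for p in pyr],
                        ScoreWeights(), shape=(64, 64))
        for m in am.per_scale:
            assert np.abs(m).max() < 1e-6
        assert np.abs(am.fused).max() < 1e-6
        assert am.image_score < 1e-6


def _rotate_half(F, ang):
    """Rotate the first half of the channels against the second half."""
    c = F.shape[0]
    Fh = F.copy()
    Fh[: c // 2] = np.cos(ang) * F[: c // 2] + np.sin(ang) * F[c // 2:]
    Fh[c // 2:] = -np.sin(ang) * F[: c // 2] + np.cos(ang) * F[c // 2:]
    return Fh


def make_pairs(rng, n=12, euclid="none", cosine="none"):
    """Single-scale validation pairs with each distance channel carrying
    either the class signal ("signal"), pure class-independent noise
    ("noise"), or neither ("none")."""
    pairs, labels = [], []
    mag = 10.0 if euclid == "noise" else 0.05 if cosine == "noise" else 1.0
    for i in range(2 * n):
        defective = i < n
        F = mag * rng.normal(size=(4, 8, 8))
        scale, ang = 1.0, 0.0
        if euclid == "signal":
            scale = 1.5 if defective else 1.0 + 0.01 * rng.standard_normal()
        elif euclid == "noise":
            scale = 1.0 + 0.5 * abs(rng.standard_normal())
        if cosine == "signal":
            ang = 1.2 if defective else 0.02 * rng.standard_normal()
        elif cosine == "noise":
            ang = 0.6 * rng.standard_normal()
        if euclid == "signal" and cosine == "signal":
            scale = (1.25 if defective else 1.0) + 0.1 * rng.standard_normal()
            ang = (0.5 if defective else 0.0) + 0.2 * rng.standard_normal()
        pairs.append(([F], [_rotate_half(F * scale, ang)]))
        labels.append(int(defective))
    return pairs, labels


class TestFitFusion:
    def test_returns_grid_point_and_determinism(self, rng):
        pairs, labels = make_pairs(rng, 8, euclid="signal", cosine="signal")
        w1 = fit_fusion_params(pairs, labels, shape=(8, 8), gamma=(1,),
                               fit_omega=False)
        w2 = fit_fusion_params(pairs, labels, shape=(8, 8), gamma=(1,),
                               fit_omega=False)
        assert any(np.isclose(w1.lam, g) for g in np.arange(0, 1.01, 0.05))
        assert w1.lam == w2.lam

    def test_euclid_only_signal_selects_lambda_one(self, rng):
        pairs, labels = make_pairs(rng, euclid="signal", cosine="noise")
        w = fit_fusion_params(pairs, labels, shape=(8, 8), gamma=(1,),
                              fit_omega=False)
        assert w.lam == 1.0

    def test_cosine_only_signal_selects_lambda_zero(self, rng):
        pairs, labels = make_pairs(rng, euclid="noise", cosine="signal")
        w = fit_fusion_params(pairs, labels, shape=(8, 8), gamma=(1,),
                              fit_omega=False)
        assert w.lam == 0.0

    def test_both_signals_select_interior_lambda(self, rng):
        pairs, labels = make_pairs(rng, euclid="signal", cosine="signal")
        w = fit_fusion_params(pairs, labels, shape=(8, 8), gamma=(1,),
                              fit_omega=False)
        assert 0.0 < w.lam < 1.0

    def test_one_class_rejected(self, rng):
        pairs, labels = make_pairs(rng, 0, euclid="none")
        labels = [0] * len(labels)
        with pytest.raises(ValueError):
            fit_fusion_params(pairs or [([np.ones((4, 8, 8))],
                                         [np.ones((4, 8, 8))])] * 4,
                              [0, 0, 0, 0], shape=(8, 8), gamma=(1,))

    def test_omega_softmax_normalised(self, rng):
        pairs, labels = make_pairs(rng, 8, euclid="signal", cosine="signal")
        w = fit_fusion_params(pairs, labels, shape=(8, 8), gamma=(1,),
                              fit_omega=True)
        assert np.all(w.omega >= 0)
        np.testing.assert_allclose(w.omega.sum(), 1.0, atol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_scale_map_is_convex_combination(seed):
    rng = np.random.default_rng(seed)
    dE, dC = rng.random((4, 4)), rng.random((4, 4))
    lam = rng.random()
    M = scale_map(dE, dC, lam)
    assert np.all(M >= np.minimum(dE, dC) - 1e-12)
    assert np.all(M <= np.maximum(dE, dC) + 1e-12)
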