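"""Schedule construction, forward/reverse process identities and training."""

import numpy as np
import pytest

from tabanom.codec import IdentityCodec
from tabanom.diffusion import (NoiseSchedule, ddim_step, fit_diffusion,
                               make_schedule, q_sample, reconstruct,
                               reverse_step, simple_loss)
from tabanom.unet import UNetDenoiser


class TestSchedule:
    def test_single_step_product(self):
        s = make_schedule(1, 0.1, 0.1)
        np.testing.assert_allclose(s.alpha_bars, [0.9])

    def test_hand_cumulative_product(self):
        s = make_schedule(2, 0.1, 0.2)
        np.testing.assert_allclose(s.betas, [0.1, 0.2])
        np.testing.assert_allclose(s.alpha_bars, [0.9, 0.72])

    def test_alpha_bars_strictly_decreasing(self):
        s = make_schedule(50, 1e-4, 0.3)
        assert np.all(np.diff(s.alpha_bars) < 0)
        assert np.all((s.alpha_bars > 0) & (s.alpha_bars < 1))

    @pytest.mark.parametrize("args", [
        dict(T=0, beta_start=0.1, beta_end=0.2),
        dict(T=10, beta_start=0.0, beta_end=0.2),
        dict(T=10, beta_start=0.3, beta_end=0.2),
        dict(T=10, beta_start=0.3, beta_end=1.0),
        dict(T=10, beta_start=0.1, beta_end=0.2, kind="cosine"),
    ])
    def test_invalid_inputs_raise(self, args):
        with pytest.raises(ValueError):
            make_schedule(**args)


class TestForward:
    def test_scalar_hand_value(self):
        # abar = 0.25: 0.5*2.0 + sqrt(0.75)*1.0
        s = make_schedule(1, 0.75, 0.75)
        out = q_sample(np.array(2.0), 0, np.array(1.0), s)
        np.testing.assert_allclose(out, 1.8660254, atol=1e-6)

    def test_zero_noise_scaling(self):
        s = make_schedule(1, 0.36, 0.36)  # abar = 0.64
        z0 = np.arange(12.0).reshape(3, 2, 2)
        np.testing.assert_allclose(q_sample(z0, 0, np.zeros_like(z0), s), 0.8 * z0)

    def test_near_identity_limit(self):
        s = make_schedule(1, 1e-12, 1e-12)
        z0 = np.random.default_rng(1).normal(size=(2, 4, 4))
        eps = np.random.default_rng(2).normal(size=(2, 4, 4))
        np.testing.assert_allclose(q_sample(z0, 0, eps, s), z0, atol=1e-5)

    def test_shape_mismatch_raises(self):
        s = make_schedule(2, 0.1, 0.2)
        with pytest.raises(ValueError):
            q_sample(np.zeros((2, 3)), 0, np.zeros((3, 2)), s)
        with pytest.raises(ValueError):
            q_sample(np.zeros(3), 5, np.zeros(3), s)

    def test_forward_marginal_moments(self):
        """Empirical mean/var over many draws match the closed-form marginal."""
        s = make_schedule(100, 1e-3, 0.2)
        t, z0, n = 57, 1.3, 10_000
        rng = np.random.default_rng(0)
        draws = q_sample(np.full(n, z0), t, rng.standard_normal(n), s)
        ab = s.alpha_bars[t]
        se_mean = np.sqrt(1 - ab) / np.sqrt(n)
        assert abs(draws.mean() - np.sqrt(ab) * z0) < 3 * se_mean
        se_var = (1 - ab) * np.sqrt(2.0 / (n - 1))
        assert abs(draws.var(ddof=1) - (1 - ab)) < 3 * se_var


class TestReverse:
    # alpha_t = 0.96, abar_t = 0.5 at step t=2 of this hand-built schedule
    _betas = np.array([1 - 0.5 / 0.96, 0.04])
    SCHED = NoiseSchedule(T=2, betas=_betas, alphas=1 - _betas,
                          alpha_bars=np.cumprod(1 - _betas))

    def test_standard_hand_value(self):
        out = reverse_step(np.array(1.0), 2, np.array(0.2), self.SCHED,
                           mode="standard")
        expect = (1.0 - 0.04 / np.sqrt(0.5) * 0.2) / np.sqrt(0.96)
        np.testing.assert_allclose(out, expect, atol=1e-9)
        np.testing.assert_allclose(out, 1.00907, atol=5e-6)

    def test_paper_literal_hand_value(self):
        out = reverse_step(np.array(1.0), 2, np.array(0.2), self.SCHED,
                           mode="paper_literal")
        expect = (1.0 - 0.04 * 0.2) / np.sqrt(0.96)
        np.testing.assert_allclose(out, expect, atol=1e-9)
        np.testing.assert_allclose(out, 1.01245, atol=1e-5)

    def test_modes_differ_by_vanishing_margin_for_small_beta(self):
        """The literal update deviates from the standard one by
        (sqrt(beta)-beta)*eps/sqrt(alpha), which vanishes as beta -> 0."""
        zt, eps = np.array(0.7), np.array(-0.3)
        gaps = []
        for beta in (0.2, 0.02, 0.002):
            s = make_schedule(1, beta, beta)
            a = reverse_step(zt, 1, eps, s, mode="standard")
            b = reverse_step(zt, 1, eps, s, mode="paper_literal")
            expect = (np.sqrt(beta) - beta) / np.sqrt(1 - beta) * eps
            np.testing.assert_allclose(b - a, expect, atol=1e-12)
            gaps.append(abs(b - a))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_single_step_inversion_with_true_noise(self):
        """q_sample then reverse_step from t=1 with the exact noise is identity."""
        s = make_schedule(1, 0.15, 0.15)
        rng = np.random.default_rng(3)
        z0 = rng.normal(size=(3, 8, 8))
        eps = rng.normal(size=(3, 8, 8))
        zt = q_sample(z0, 0, eps, s)
        np.testing.assert_allclose(reverse_step(zt, 1, eps, s), z0, atol=1e-5)

    def test_ddim_inverts_any_step_with_true_noise(self):
        s = make_schedule(100, 1e-3, 0.2)
        rng = np.random.default_rng(4)
        z0 = rng.normal(size=(2, 4, 4))
        eps = rng.normal(size=(2, 4, 4))
        for t in (1, 17, 60, 100):
            zt = q_sample(z0, t - 1, eps, s)
            np.testing.assert_allclose(ddim_step(zt, t, 0, eps, s), z0, atol=1e-8)

    def test_invalid_step_raises(self):
        with pytest.raises(ValueError):
            reverse_step(np.zeros(2), 0, np.zeros(2), self.SCHED)
        with pytest.raises(ValueError):
            reverse_step(np.zeros(2), 1, np.zeros(2), self.SCHED, mode="other")


class TestLoss:
    def test_identity_is_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 4))
        assert simple_loss(x, x) == 0.0

    def test_hand_value(self):
        assert simple_loss(np.array([1.0, 0.0]), np.array([0.0, 0.0])) == 0.5

    def test_nonnegative_and_mismatch(self):
        rng = np.random.default_rng(1)
        assert simple_loss(rng.normal(size=5), rng.normal(size=5)) >= 0
        with pytest.raises(ValueError):
            simple_loss(np.zeros(3), np.zeros(4))


class _OracleDenoiser:
    """Returns the exact injected noise regardless of input (test double)."""

    def __init__(self, eps):
        self.eps = eps

    def __call__(self, zt, t, ar=None):
        from tabanom.nn import Tensor
        return Tensor(np.broadcast_to(self.eps, zt.shape).copy())


class TestReconstruct:
    def test_t_start_zero_is_codec_roundtrip(self, tablet64):
        codec = IdentityCodec()
        s = make_schedule(10, 1e-3, 0.2)
        out = reconstruct(tablet64, None, None, codec, s, t_start=0)
        np.testing.assert_array_equal(out, tablet64.image)

    def test_oracle_denoiser_recovers_input(self, tablet64):
        """Forward then exact reverse with the true noise returns the image."""
        codec = IdentityCodec()
        s = make_schedule(20, 1e-3, 0.1)
        rng = np.random.default_rng(5)
        # pre-draw the noise reconstruct() will sample with an equal-state rng
        probe = np.random.default_rng(5)
        eps = probe.standard_normal((1, 3, 64, 64)).astype(np.float32)
        out = reconstruct(tablet64, _OracleDenoiser(eps), None, codec, s,
                          t_start=10, rng=rng)
        err = np.abs(out - tablet64.image).max()
        assert err <= 1e-3

    def test_untrained_learned_codec_rejected(self, tablet64):
        from tabanom.codec import CodecConfig, ConvCodec
        from tabanom.pipeline import build_models  # noqa: F401  (import check)
        codec = ConvCodec(CodecConfig(mode="learned", latent_channels=4,
                                      downscale=4))
        assert codec.trained is False


def test_training_reduces_loss_smoke():
    """A few epochs on flat images reduce the noise-prediction loss."""
    rng = np.random.default_rng(0)
    imgs = np.clip(0.5 + 0.05 * rng.standard_normal((16, 3, 16, 16)), 0, 1)
    den = UNetDenoiser(3, widths=(8, 8, 8, 8), seed=0)
    s = make_schedule(50, 1e-3, 0.2)
    hist = fit_diffusion(imgs.astype(np.float32), den, None, IdentityCodec(),
                         s, epochs=5, batch_size=8, seed=0)
    assert hist[-1] < hist[0]
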