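"""Denoising-diffusion core: schedule, forward noising, reverse steps, loss,
and full test-time reconstruction.

The forward process destroys an image (or its latent) with Gaussian noise
under a variance schedule ``beta_t``; a denoiser is trained to predict the
injected noise, and at test time a partially re-noised input is denoised
back, conditioned on features of the original image, so that defects — which
the model has never seen — are replaced by normal appearance.

Two reverse-step conventions are provided.  ``standard`` is the DDPM
posterior mean,

    z_{t-1} = (z_t - (1-alpha_t)/sqrt(1-alpha_bar_t) * eps_hat) / sqrt(alpha_t),

``paper_literal`` drops the ``1/sqrt(1-alpha_bar_t)`` factor,

    z_{t-1} = (z_t - (1-alpha_t) * eps_hat) / sqrt(alpha_t),

a variant that circulates in some write-ups of latent diffusion; the two
coincide whenever ``alpha_bar_t == alpha_t``.  ``standard`` is the default.

Index conventions: :func:`q_sample` takes a 0-based table index
(``alpha_bars[t]`` is the marginal after ``t+1`` forward steps), while
:func:`reverse_step` and :func:`ddim_step` count steps 1-based — a state
carrying ``alpha_bars[t-1]`` worth of noise sits at step ``t``, and stepping
from ``t=1`` lands on the clean sample.  With a T=1 schedule
``alpha_bar_1 == alpha_1``, where the two reverse modes coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, no_grad

__all__ = [
    "NoiseSchedule", "make_schedule", "q_sample", "reverse_step", "ddim_step",
    "simple_loss", "reconstruct", "reconstruct_batch", "fit_diffusion",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Tables beta_t / alpha_t / alpha_bar_t indexed by diffusion step."""

    T: int
    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray

    def __post_init__(self):
        if self.T < 1 or len(self.betas) != self.T:
            raise ValueError("schedule length must equal T >= 1")
        b = np.asarray(self.betas, dtype=np.float64)
        if np.any(b <= 0) or np.any(b >= 1):
            raise ValueError("betas must lie strictly inside (0, 1)")
        if not np.allclose(self.alphas, 1.0 - b):
            raise ValueError("alphas must equal 1 - betas")
        if not np.allclose(self.alpha_bars, np.cumprod(self.alphas)):
            raise ValueError("alpha_bars must be the cumulative product of alphas")


def make_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 0.02,
                  kind: str = "linear") -> NoiseSchedule:
    """Build a variance schedule; ``linear`` interpolates inclusive endpoints."""
    if kind != "linear":
        raise ValueError(f"unknown schedule kind: {kind!r}")
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError("need 0 < beta_start <= beta_end < 1")
    betas = np.linspace(beta_start, beta_end, T, dtype=np.float64)
    alphas = 1.0 - betas
    return NoiseSchedule(T=T, betas=betas, alphas=alphas,
                         alpha_bars=np.cumprod(alphas))


def _per_sample(coeff: np.ndarray, t, z: np.ndarray) -> np.ndarray:
    """Gather schedule coefficients for scalar or per-sample t, shaped to z."""
    tt = np.asarray(t)
    c = coeff[tt]
    if tt.ndim == 0:
        return c
    return c.reshape((-1,) + (1,) * (z.ndim - 1))


def q_sample(z0: np.ndarray, t, eps: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Forward noising: sqrt(abar_t) z0 + sqrt(1 - abar_t) eps."""
    if np.asarray(eps).shape != np.asarray(z0).shape:
        raise ValueError("eps must have the same shape as z0")
    if np.any(np.asarray(t) < 0) or np.any(np.asarray(t) >= schedule.T):
        raise ValueError("t out of range")
    ab = _per_sample(schedule.alpha_bars, t, z0)
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps


def reverse_step(zt: np.ndarray, t: int, eps_pred: np.ndarray,
                 schedule: NoiseSchedule, mode: str = "standard",
                 noise: np.ndarray | None = None) -> np.ndarray:
    """One reverse step z_t -> z_{t-1}; deterministic unless noise is given."""
    if t < 1:
        raise ValueError("reverse_step needs t >= 1 (cannot step below z0)")
    if t > schedule.T:
        raise ValueError("t exceeds the schedule length")
    a = schedule.alphas[t - 1]
    ab = schedule.alpha_bars[t - 1]
    if mode == "standard":
        mean = (zt - (1.0 - a) / np.sqrt(1.0 - ab) * eps_pred) / np.sqrt(a)
    elif mode == "paper_literal":
        mean = (zt - (1.0 - a) * eps_pred) / np.sqrt(a)
    else:
        raise ValueError(f"unknown reverse mode: {mode!r}")
    if noise is not None:
        ab_prev = schedule.alpha_bars[t - 2] if t >= 2 else 1.0
        sigma = np.sqrt(schedule.betas[t - 1] * (1.0 - ab_prev) / (1.0 - ab))
        mean = mean + sigma * noise
    return mean


def ddim_step(zt: np.ndarray, t: int, t_prev: int, eps_pred: np.ndarray,
              schedule: NoiseSchedule, clip: tuple | None = None) -> np.ndarray:
    """Deterministic strided step t -> t_prev, 1-based (t_prev = 0 is z0).

    Predicts z0 from the noise estimate and re-applies the forward marginal
    at t_prev; with t_prev == t-1 it is the eta=0 sampler, and with the true
    injected noise it inverts q_sample exactly in a single step.

    ``clip=(lo, hi)`` bounds the intermediate clean-state prediction to the
    data range, preventing the 1/sqrt(alpha_bar) amplification of noise the
    denoiser failed to explain — the usual clip-denoised stabilisation.
    """
    if not 1 <= t <= schedule.T or not 0 <= t_prev < t:
        raise ValueError("need 0 <= t_prev < t <= T")
    ab_t = schedule.alpha_bars[t - 1]
    ab_p = 1.0 if t_prev == 0 else schedule.alpha_bars[t_prev - 1]
    z0_pred = (zt - np.sqrt(1.0 - ab_t) * eps_pred) / np.sqrt(ab_t)
    if clip is not None:
        z0_pred = np.clip(z0_pred, clip[0], clip[1])
    return np.sqrt(ab_p) * z0_pred + np.sqrt(1.0 - ab_p) * eps_pred


def simple_loss(eps, eps_pred):
    """Mean squared error between injected and predicted noise.

    Accepts numpy arrays (returns float) or engine Tensors (returns a Tensor
    for backprop).
    """
    if isinstance(eps_pred, Tensor):
        target = eps if isinstance(eps, Tensor) else Tensor(np.asarray(eps, dtype=eps_pred.dtype))
        if target.shape != eps_pred.shape:
            raise ValueError("shape mismatch between eps and eps_pred")
        return (eps_pred - target).square().mean()
    eps = np.asarray(eps)
    eps_pred = np.asarray(eps_pred)
    if eps.shape != eps_pred.shape:
        raise ValueError("shape mismatch between eps and eps_pred")
    return float(np.mean((eps - eps_pred) ** 2))


def _eps_of(denoiser, ar_net, z: np.ndarray, t_step: int, x: np.ndarray) -> np.ndarray:
    """Noise prediction at 1-based step t_step (time-embeds the 0-based index)."""
    ts = np.full(z.shape[0], t_step - 1, dtype=np.int64)
    with no_grad():
        if ar_net is not None:
            feats = ar_net(Tensor(x), Tensor(z), ts)
        else:
            feats = None
        return denoiser(Tensor(z), ts, ar=feats).data


def reconstruct_batch(x: np.ndarray, denoiser, ar_net, codec,
                      schedule: NoiseSchedule, t_start: int,
                      rng: np.random.Generator, mode: str = "standard",
                      sample_steps: int | None = None,
                      clip: tuple | None = (0.0, 1.0)) -> np.ndarray:
    """Reconstruct a batch of images (N,3,H,W in [0,1]) through the model.

    Encodes, noises to step ``t_start`` (number of forward steps taken),
    denoises deterministically conditioned on the original images, decodes.

    The reverse trajectory uses deterministic (eta=0) ddim steps — the only
    deterministic rule whose single step exactly inverts q_sample given the
    true noise — visiting ``sample_steps`` evenly spaced steps (all of them
    when ``sample_steps`` is None).  ``mode="paper_literal"`` instead walks
    every step with the literal printed update of :func:`reverse_step`, for
    fidelity comparisons.
    """
    if not (0 <= t_start <= schedule.T):
        raise ValueError("t_start must lie in [0, T]")
    x = np.asarray(x, dtype=np.float32)
    z = codec.encode(x)
    if t_start > 0:
        eps = rng.standard_normal(z.shape).astype(z.dtype)
        z = q_sample(z, t_start - 1, eps, schedule)   # state at 1-based step t_start
        if mode == "paper_literal":
            for t_step in range(t_start, 0, -1):
                e = _eps_of(denoiser, ar_net, z, t_step, x)
                z = reverse_step(z, t_step, e, schedule, mode=mode)
        else:
            n_steps = t_start if sample_steps is None else min(sample_steps, t_start)
            ts = np.unique(np.linspace(1, t_start, n_steps).round().astype(int))[::-1]
            for i, t_step in enumerate(ts):
                t_prev = ts[i + 1] if i + 1 < len(ts) else 0
                e = _eps_of(denoiser, ar_net, z, t_step, x)
                z = ddim_step(z, t_step, t_prev, e, schedule, clip=clip)
    return codec.decode(z)


def reconstruct(x, denoiser, ar_net, codec, schedule: NoiseSchedule,
                t_start: int, rng: np.random.Generator | None = None,
                mode: str = "standard", sample_steps: int | None = None) -> np.ndarray:
    """Single-image wrapper around :func:`reconstruct_batch`.

    ``x`` may be an HWC array in [0,1] or an object with an ``image``
    attribute holding one; returns the reconstruction in the same HWC layout.
    """
    img = getattr(x, "image", x)
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HWC RGB image")
    if rng is None:
        rng = np.random.default_rng(0)
    nchw = img.transpose(2, 0, 1)[None]
    out = reconstruct_batch(nchw, denoiser, ar_net, codec, schedule, t_start,
                            rng, mode=mode, sample_steps=sample_steps)
    return out[0].transpose(1, 2, 0)


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random dihedral-group augmentation (flips + 90-degree rotations)."""
    out = x.copy()
    for i in range(len(out)):
        k = int(rng.integers(4))
        if k:
            out[i] = np.rot90(out[i], k, axes=(1, 2))
        if rng.random() < 0.5:
            out[i] = out[i][:, :, ::-1]
    return np.ascontiguousarray(out)


def fit_diffusion(train_images: np.ndarray, denoiser, ar_net, codec,
                  schedule: NoiseSchedule, epochs: int = 30,
                  batch_size: int = 8, lr: float = 1e-2, seed: int = 0,
                  clip_norm: float = 1.0, t_max: int | None = None,
                  augment: bool = True, ema_decay: float = 0.995,
                  callback=None) -> list[float]:
    """Train denoiser (and AR network, if given) with the simplified noise
    loss on normal images only.

    ``train_images`` is (N,3,H,W) in [0,1] — no masks or labels enter here,
    preserving the unsupervised setting.  Uses Adam with global-norm
    gradient clipping, a half-cosine learning-rate decay, optional dihedral
    augmentation, and an exponential moving average of the weights that is
    loaded back into the models at the end (standard practice for
    short-budget diffusion training).  ``t_max`` restricts the sampled
    timesteps to the range a partial re-noising sampler will actually
    visit.  Returns per-epoch mean losses.
    """
    from .nn import Adam

    train_images = np.asarray(train_images, dtype=np.float32)
    if train_images.ndim != 4:
        raise ValueError("train_images must be (N,3,H,W)")
    rng = np.random.default_rng(seed)
    t_hi = schedule.T if t_max is None else min(t_max, schedule.T)
    params = list(denoiser.parameters())
    if ar_net is not None:
        params += list(ar_net.parameters())
    opt = Adam(params, lr=lr)
    ema = [p.data.copy() for p in params] if ema_decay else None
    n = len(train_images)
    total_steps = max(1, epochs * ((n + batch_size - 1) // batch_size))
    step = 0
    history: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            x = train_images[idx]
            if augment:
                x = _augment_batch(x, rng)
            z0 = codec.encode(x)
            t = rng.integers(0, t_hi, size=len(idx))
            eps = rng.standard_normal(z0.shape).astype(np.float32)
            zt = q_sample(z0, t, eps, schedule).astype(np.float32)
            if ar_net is not None:
                feats = ar_net(Tensor(x), Tensor(zt), t)
            else:
                feats = None
            pred = denoiser(Tensor(zt), t, ar=feats)
            loss = simple_loss(eps, pred)
            opt.zero_grad()
            loss.backward()
            if clip_norm:
                gn = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params
                                 if p.grad is not None))
                if gn > clip_norm:
                    scale = clip_norm / gn
                    for p in params:
                        if p.grad is not None:
                            p.grad *= scale
            opt.lr = lr * 0.5 * (1.0 + np.cos(np.pi * step / total_steps))
            opt.step()
            if ema is not None:
                for e, p in zip(ema, params):
                    e *= ema_decay
                    e += (1.0 - ema_decay) * p.data
            step += 1
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        if callback is not None:
            callback(epoch, history[-1])
    if ema is not None:
        for e, p in zip(ema, params):
            p.data = e
    return history
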