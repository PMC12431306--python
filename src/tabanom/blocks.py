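"""Building blocks shared by the denoiser and the assisted-reconstruction
encoder: time-conditioned residual blocks, single-head self-attention, and
the sinusoidal timestep embedding."""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, GroupNorm, Linear, Module, Tensor

__all__ = ["timestep_embedding", "TimeMLP", "ResBlock", "SelfAttention2d"]


def timestep_embedding(t, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Sinusoidal embedding of integer timesteps, shape (N, dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    ang = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.cos(ang), np.sin(ang)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((len(t), 1))], axis=1)
    return emb.astype(np.float32)


class TimeMLP(Module):
    """Two-layer projection of the sinusoidal embedding."""

    def __init__(self, dim: int, rng: np.random.Generator, dtype=np.float32):
        self.dim = dim
        self.fc1 = Linear(dim, dim, rng, dtype=dtype)
        self.fc2 = Linear(dim, dim, rng, dtype=dtype)

    def forward(self, t) -> Tensor:
        emb = Tensor(timestep_embedding(t, self.dim).astype(self.fc1.w.dtype))
        return self.fc2(self.fc1(emb).silu())


class ResBlock(Module):
    """norm -> silu -> conv -> (+ time) -> norm -> silu -> conv, residual."""

    def __init__(self, c_in: int, c_out: int, t_dim: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.n1 = GroupNorm(c_in, dtype=dtype)
        self.c1 = Conv2d(c_in, c_out, 3, rng, padding=1, dtype=dtype)
        self.t_proj = Linear(t_dim, c_out, rng, dtype=dtype) if t_dim else None
        self.n2 = GroupNorm(c_out, dtype=dtype)
        self.c2 = Conv2d(c_out, c_out, 3, rng, padding=1, dtype=dtype)
        self.c2.w.data[...] = 0.0   # start as an identity residual: stabilises early training
        self.skip = Conv2d(c_in, c_out, 1, rng, dtype=dtype) if c_in != c_out else None

    def forward(self, x: Tensor, t_emb: Tensor | None = None) -> Tensor:
        h = self.c1(self.n1(x).silu())
        if self.t_proj is not None and t_emb is not None:
            N, c = t_emb.shape[0], h.shape[1]
            h = h + self.t_proj(t_emb).reshape(N, c, 1, 1)
        h = self.c2(self.n2(h).silu())
        res = x if self.skip is None else self.skip(x)
        return h + res


class SelfAttention2d(Module):
    """Single-head dot-product self-attention over spatial positions."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float32):
        self.channels = channels
        self.norm = GroupNorm(channels, dtype=dtype)
        self.q = Conv2d(channels, channels, 1, rng, dtype=dtype)
        self.k = Conv2d(channels, channels, 1, rng, dtype=dtype)
        self.v = Conv2d(channels, channels, 1, rng, dtype=dtype)
        self.proj = Conv2d(channels, channels, 1, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        h = self.norm(x)
        q = self.q(h).reshape(N, C, H * W).transpose(0, 2, 1)
        k = self.k(h).reshape(N, C, H * W)
        v = self.v(h).reshape(N, C, H * W).transpose(0, 2, 1)
        att = ((q @ k) * (1.0 / np.sqrt(C))).softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1).reshape(N, C, H, W)
        return x + self.proj(out)
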