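"""Image <-> latent codec.

Diffusion can run directly in pixel space (``identity`` mode, the default at
desk scale) or in the latent space of a small strided convolutional
autoencoder (``learned`` mode) trained on normal images with a mean-squared
reconstruction loss and frozen afterwards.  The codec is deliberately plain
— no KL term, no adversarial loss — because its only job here is a compact,
invertible-enough representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Conv2d, GroupNorm, Module, Tensor, no_grad

__all__ = ["CodecConfig", "IdentityCodec", "ConvCodec", "build_codec", "fit_codec"]

_ALLOWED_F = (1, 2, 4, 8)


@dataclass(frozen=True)
class CodecConfig:
    latent_channels: int = 4
    downscale: int = 4
    mode: str = "identity"

    def __post_init__(self):
        if self.mode not in ("identity", "learned"):
            raise ValueError(f"unknown codec mode {self.mode!r}")
        if self.downscale not in _ALLOWED_F:
            raise ValueError(f"downscale must be one of {_ALLOWED_F}")
        if self.mode == "identity" and (self.latent_channels != 3 or self.downscale != 1):
            raise ValueError("identity mode forces latent_channels=3, downscale=1")


class IdentityCodec:
    """Pixel-space pass-through; decode clamps to [0,1]."""

    config = CodecConfig(latent_channels=3, downscale=1, mode="identity")
    trained = True

    def encode(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        self._check(x)
        return x.copy()

    def decode(self, z: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(z, dtype=np.float32), 0.0, 1.0)

    @staticmethod
    def _check(x):
        if x.shape[-3] != 3:
            raise ValueError("identity codec expects 3-channel input")

    def parameters(self):
        return iter(())

    def state_dict(self):
        return {}


class ConvCodec(Module):
    """Small strided conv autoencoder; sigmoid decoder output keeps [0,1]."""

    def __init__(self, config: CodecConfig, seed: int = 0, width: int = 32):
        if config.mode != "learned":
            raise ValueError("ConvCodec requires mode='learned'")
        self.config = config
        self.trained = False
        rng = np.random.default_rng(seed)
        f, c = config.downscale, config.latent_channels
        n_down = int(np.log2(f))
        enc, ch = [], 3
        for i in range(n_down):
            out = width * (i + 1)
            enc.append(Conv2d(ch, out, 3, rng, stride=2, padding=1))
            ch = out
        self._enc_convs = enc
        self._enc_norms = [GroupNorm(c_.w.shape[0]) for c_ in enc]
        self._to_latent = Conv2d(ch if n_down else 3, c, 3, rng, padding=1)
        self._from_latent = Conv2d(c, ch if n_down else width, 3, rng, padding=1)
        dec, ch_d = [], (ch if n_down else width)
        for i in range(n_down):
            out = width * (n_down - i - 1) if i < n_down - 1 else width
            dec.append(Conv2d(ch_d, out, 3, rng, padding=1))
            ch_d = out
        self._dec_convs = dec
        self._dec_norms = [GroupNorm(c_.w.shape[0]) for c_ in dec]
        self._out = Conv2d(ch_d, 3, 3, rng, padding=1)
        # expose for parameter traversal
        for i, m in enumerate(enc):
            setattr(self, f"enc{i}", m)
        for i, m in enumerate(self._enc_norms):
            setattr(self, f"encn{i}", m)
        for i, m in enumerate(dec):
            setattr(self, f"dec{i}", m)
        for i, m in enumerate(self._dec_norms):
            setattr(self, f"decn{i}", m)
        self.to_latent = self._to_latent
        self.from_latent = self._from_latent
        self.out = self._out

    # -- differentiable paths -------------------------------------------------
    def encode_t(self, x: Tensor) -> Tensor:
        h = x
        for conv, norm in zip(self._enc_convs, self._enc_norms):
            h = norm(conv(h)).silu()
        return self._to_latent(h)

    def decode_t(self, z: Tensor) -> Tensor:
        h = self._from_latent(z).silu()
        for conv, norm in zip(self._dec_convs, self._dec_norms):
            h = norm(conv(h.upsample_nearest(2))).silu()
        return self._out(h).sigmoid()

    # -- frozen numpy surface -------------------------------------------------
    def encode(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        f = self.config.downscale
        if x.shape[-1] % f or x.shape[-2] % f:
            raise ValueError(f"spatial dims {x.shape[-2:]} not divisible by f={f}")
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        with no_grad():
            z = self.encode_t(Tensor(x)).data
        return z[0] if squeeze else z

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float32)
        if z.shape[-3] != self.config.latent_channels:
            raise ValueError("latent channel mismatch")
        squeeze = z.ndim == 3
        if squeeze:
            z = z[None]
        with no_grad():
            x = self.decode_t(Tensor(z)).data
        return np.clip(x[0] if squeeze else x, 0.0, 1.0)


def build_codec(config: CodecConfig, seed: int = 0):
    if config.mode == "identity":
        return IdentityCodec()
    return ConvCodec(config, seed=seed)


def fit_codec(images: np.ndarray, codec, epochs: int = 20, batch_size: int = 16,
              lr: float = 2e-3, seed: int = 0, val_frac: float = 0.1,
              callback=None):
    """Train a learned codec on normal images (N,3,H,W in [0,1]).

    Returns (train_losses, val_losses) per epoch; identity codecs are a
    warned no-op.
    """
    import warnings

    if isinstance(codec, IdentityCodec):
        warnings.warn("fit_codec called on an identity codec; nothing to train")
        return [], []
    images = np.asarray(images, dtype=np.float32)
    if len(images) < 1:
        raise ValueError("need at least one training image")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(images))
    n_val = max(1, int(len(images) * val_frac)) if len(images) > 1 else 0
    val, train = images[order[:n_val]], images[order[n_val:]]
    if len(train) == 0:
        train, val = val, train
    opt = Adam(codec.parameters(), lr=lr)
    tr_hist, va_hist = [], []

    def _loss_of(batch):
        xt = Tensor(batch)
        return (codec.decode_t(codec.encode_t(xt)) - xt).square().mean()

    for epoch in range(epochs):
        idx = rng.permutation(len(train))
        losses = []
        for lo in range(0, len(train), batch_size):
            loss = _loss_of(train[idx[lo:lo + batch_size]])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        tr_hist.append(float(np.mean(losses)))
        if len(val):
            with no_grad():
                va_hist.append(_loss_of(val).item())
        if callback is not None:
            callback(epoch, tr_hist[-1])
    codec.trained = True
    return tr_hist, va_hist
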