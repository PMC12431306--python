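"""Scale Fusion (SF) feature extractor.

A four-stage hierarchical feature extractor in the ConvNeXt idiom that
produces the pyramid used for anomaly measurement:

* stage 1 — patchify stem (4x4 conv, stride 4), then a 7x7 depthwise
  convolution -> channelwise LayerNorm -> GELU -> 1x1 pointwise, with a
  residual around the stem output: F1 at H/4;
* stage 2 — patch-merging downsample (2x2, stride 2) and a stack of three
  3x3 depthwise convolutions -> LN -> GELU -> pointwise, residual: F2 at H/8;
* stage 3 — downsample and a dilated 3x3 depthwise convolution (d=2) for a
  wider receptive field, residual: F3 at H/16;
* stage 4 — downsample, 7x7 depthwise -> LN -> GELU -> pointwise, residual,
  then global average pooling: F4 at 1x1.

The same (Siamese) instance embeds both the input image and its
reconstruction; anomalies surface as distances between the two pyramids.
Training is self-supervised on normal images: a throwaway decoder is
attached to F3 and the network minimises image reconstruction error
(``autoencode`` strategy); ``random`` keeps the seeded initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Adam, ChannelLayerNorm, Conv2d, Module, ModuleList, Tensor,
                 no_grad)

__all__ = ["FeaturePyramid", "SFNetwork", "fit_sf"]


@dataclass
class FeaturePyramid:
    """F1..F4 at scales 1/4, 1/8, 1/16 and global (1x1)."""

    levels: list  # four numpy arrays, (N, Ci, Hi, Wi)

    def __post_init__(self):
        if len(self.levels) != 4:
            raise ValueError("a feature pyramid has exactly 4 levels")

    def __iter__(self):
        return iter(self.levels)

    def __getitem__(self, i):
        return self.levels[i]


class _HFEBlock(Module):
    """depthwise conv -> LN -> GELU -> pointwise, plus identity residual."""

    def __init__(self, c: int, k: int, rng, stack: int = 1, dilation: int = 1,
                 dtype=np.float32):
        pad = dilation * (k - 1) // 2
        self.dw = ModuleList(
            Conv2d(c, c, k, rng, padding=pad, dilation=dilation, groups=c, dtype=dtype)
            for _ in range(stack))
        self.ln = ChannelLayerNorm(c, dtype=dtype)
        self.pw = Conv2d(c, c, 1, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.dw:
            h = conv(h)
        return self.pw(self.ln(h).gelu()) + x


class SFNetwork(Module):
    def __init__(self, widths=(16, 32, 64, 128), seed: int = 0, dtype=np.float32):
        if len(widths) != 4:
            raise ValueError("SFNetwork needs 4 stage widths")
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        c1, c2, c3, c4 = widths
        self.stem = Conv2d(3, c1, 4, rng, stride=4, dtype=dtype)
        self.block1 = _HFEBlock(c1, 7, rng, dtype=dtype)
        self.down1 = Conv2d(c1, c2, 2, rng, stride=2, dtype=dtype)
        self.block2 = _HFEBlock(c2, 3, rng, stack=3, dtype=dtype)
        self.down2 = Conv2d(c2, c3, 2, rng, stride=2, dtype=dtype)
        self.block3 = _HFEBlock(c3, 3, rng, dilation=2, dtype=dtype)
        self.down3 = Conv2d(c3, c4, 2, rng, stride=2, dtype=dtype)
        self.block4 = _HFEBlock(c4, 7, rng, dtype=dtype)

    def forward(self, x: Tensor) -> list:
        """Differentiable pyramid; returns [F1, F2, F3, F4] Tensors."""
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"spatial dims {x.shape[2:]} must be divisible by 32")
        f1 = self.block1(self.stem(x))
        f2 = self.block2(self.down1(f1))
        f3 = self.block3(self.down2(f2))
        f4 = self.block4(self.down3(f3)).mean(axis=(2, 3), keepdims=True)
        return [f1, f2, f3, f4]

    def extract_pyramid(self, x: np.ndarray) -> FeaturePyramid:
        """Pyramid for images (3,H,W) or (N,3,H,W) in [0,1], inference mode."""
        x = np.asarray(x, dtype=np.float32)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        with no_grad():
            levels = [f.data for f in self.forward(Tensor(x))]
        if squeeze:
            levels = [f[0] for f in levels]
        return FeaturePyramid(levels=levels)


class _SFDecoder(Module):
    """Throwaway decoder from F3 back to the image, for autoencode training."""

    def __init__(self, c3: int, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        chans = [c3, c3 // 2, max(c3 // 4, 8), max(c3 // 8, 8)]
        self.convs = ModuleList(
            Conv2d(chans[i], chans[i + 1], 3, rng, padding=1, dtype=dtype)
            for i in range(3))
        self.out = Conv2d(chans[3], 3, 3, rng, padding=1, dtype=dtype)

    def forward(self, f3: Tensor) -> Tensor:
        h = f3
        for conv in self.convs:
            h = conv(h.upsample_nearest(2)).gelu()
        return self.out(h.upsample_nearest(2)).sigmoid()


def fit_sf(normal_images: np.ndarray, net: SFNetwork, strategy: str = "autoencode",
           epochs: int = 10, batch_size: int = 16, lr: float = 2e-3,
           seed: int = 0, callback=None) -> list[float]:
    """Train the SF network on normal images (N,3,H,W); returns loss history.

    ``autoencode``: attach a small decoder to F3, minimise MSE image
    reconstruction, discard the decoder.  ``random``: keep the seeded
    random initialisation (returns an empty history).
    """
    if strategy == "random":
        return []
    if strategy != "autoencode":
        raise ValueError(f"unknown SF training strategy {strategy!r}")
    normal_images = np.asarray(normal_images, dtype=np.float32)
    if normal_images.ndim != 4 or len(normal_images) < 1:
        raise ValueError("autoencode strategy needs at least one (N,3,H,W) image")
    rng = np.random.default_rng(seed)
    dec = _SFDecoder(net.widths[2], seed=seed)
    opt = Adam(list(net.parameters()) + list(dec.parameters()), lr=lr)
    history = []
    for epoch in range(epochs):
        idx = rng.permutation(len(normal_images))
        losses = []
        for lo in range(0, len(normal_images), batch_size):
            xb = Tensor(normal_images[idx[lo:lo + batch_size]])
            _, _, f3, _ = net.forward(xb)
            loss = (dec(f3) - xb).square().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        if callback is not None:
            callback(epoch, history[-1])
    return history
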