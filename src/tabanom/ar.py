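"""Assisted-Reconstruction (AR) network and SELA attention.

The AR network conditions the denoiser on the *original* image: the image is
projected to the latent resolution, summed with the noisy latent, pushed
through four time-conditioned encoding blocks (each saving a skip feature
before downsampling), and refined by a middle block of two residual layers
around a SELA attention module.  The middle feature is *added* to the
denoiser's mid-block activation; the skips are *concatenated* into the
decoder's skip connections — global and local guidance respectively.

SELA (semantic-enhanced lightweight attention) runs two branches in
parallel over a feature map X of shape C x H x W:

* channel branch: global max- and average-pooling are concatenated (2C),
  squeezed through a 1x1 bottleneck of width C/r with ReLU, expanded back
  to C and passed through a sigmoid, giving per-channel weights A_SC;
* spatial branch: a grouped 1x1 convolution (G groups) followed by a 3x3
  depthwise convolution and a 1x1 pointwise convolution, sigmoid, giving a
  full-resolution weight field A_SD.

The output is Conv1x1(Concat(X*A_SC, X*A_SD)) with the channel weights
broadcast over space.  Defaults r=4, G=4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import ResBlock, SelfAttention2d, TimeMLP
from .nn import Conv2d, Identity, Module, ModuleList, Tensor, concat

__all__ = ["SELAConfig", "SELA", "ARFeatures", "ARNetwork", "denoise_with_ar"]


@dataclass(frozen=True)
class SELAConfig:
    channels: int
    r: int = 4
    groups: int = 4

    def __post_init__(self):
        if self.r < 1:
            raise ValueError("compression ratio r must be >= 1")
        if self.channels % self.r:
            raise ValueError(f"channels ({self.channels}) not divisible by r={self.r}")
        if self.channels % self.groups:
            raise ValueError(f"channels ({self.channels}) not divisible by G={self.groups}")


class SELA(Module):
    def __init__(self, config: SELAConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(seed)
        C, r, G = config.channels, config.r, config.groups
        # channel branch
        self.sc_squeeze = Conv2d(2 * C, C // r, 1, rng, dtype=dtype)
        self.sc_expand = Conv2d(C // r, C, 1, rng, dtype=dtype)
        # spatial branch
        self.sd_group = Conv2d(C, C, 1, rng, groups=G, dtype=dtype)
        self.sd_depthwise = Conv2d(C, C, 3, rng, padding=1, groups=C, dtype=dtype)
        self.sd_pointwise = Conv2d(C, C, 1, rng, dtype=dtype)
        # fusion
        self.fuse = Conv2d(2 * C, C, 1, rng, dtype=dtype)

    def channel_attention(self, x: Tensor) -> Tensor:
        """A_SC: per-channel weights in (0,1), shape (N, C, 1, 1)."""
        pooled = concat([x.max_spatial(), x.mean(axis=(2, 3), keepdims=True)], axis=1)
        return self.sc_expand(self.sc_squeeze(pooled).relu()).sigmoid()

    def spatial_attention(self, x: Tensor) -> Tensor:
        """A_SD: spatial weight field in (0,1), shape (N, C, H, W)."""
        return self.sd_pointwise(self.sd_depthwise(self.sd_group(x))).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        a_sc = self.channel_attention(x)
        a_sd = self.spatial_attention(x)
        return self.fuse(concat([x * a_sc, x * a_sd], axis=1))


@dataclass
class ARFeatures:
    """Per-scale skip features (full -> deepest resolution) plus the middle
    feature emitted by the AR middle block."""

    skips: list
    middle: Tensor


class ARNetwork(Module):
    """Four encoding blocks + middle block producing conditioning features.

    Blocks 1-3 downsample after saving their skip; block 4 stays at the
    deepest resolution so the middle feature matches the denoiser mid block.
    Attention is applied at the two deepest levels.
    """

    def __init__(self, image_channels: int = 3, latent_channels: int = 3,
                 downscale: int = 1, widths=(32, 64, 96, 128),
                 sela: SELAConfig | None = None, attn_levels=(2, 3),
                 patchify: int = 1, seed: int = 0, dtype=np.float32):
        if len(widths) != 4:
            raise ValueError("ARNetwork needs 4 block widths")
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.patchify = patchify
        t_dim = 4 * widths[0]
        self.time = TimeMLP(t_dim, rng, dtype=dtype)
        if downscale == 1:
            self.proj = Conv2d(image_channels, latent_channels, 3, rng, padding=1, dtype=dtype)
        else:
            self.proj = Conv2d(image_channels, latent_channels, downscale, rng,
                               stride=downscale, dtype=dtype)
        packed = latent_channels * patchify * patchify
        self.conv_in = Conv2d(packed, widths[0], 3, rng, padding=1, dtype=dtype)
        self.blocks = ModuleList(
            ResBlock(widths[i], widths[i], t_dim, rng, dtype=dtype) for i in range(4))
        self.attn = ModuleList(
            SelfAttention2d(widths[i], rng, dtype=dtype) if i in attn_levels else Identity()
            for i in range(4))
        self.downs = ModuleList(
            Conv2d(widths[i], widths[i + 1], 3, rng, stride=2, padding=1, dtype=dtype)
            for i in range(3))
        sela_cfg = sela or SELAConfig(channels=widths[3])
        if sela_cfg.channels != widths[3]:
            raise ValueError("SELA channels must match the deepest block width")
        self.arm_res1 = ResBlock(widths[3], widths[3], t_dim, rng, dtype=dtype)
        self.arm_sela = SELA(sela_cfg, seed=seed + 1, dtype=dtype)
        self.arm_res2 = ResBlock(widths[3], widths[3], t_dim, rng, dtype=dtype)

    def forward(self, x: Tensor, zt: Tensor, t) -> ARFeatures:
        """Encode image x (N,3,H,W) with noisy latent zt (N,c,H/f,W/f)."""
        p = self.proj(x)
        if p.shape != zt.shape:
            raise ValueError(
                f"projected image {p.shape} incompatible with latent {zt.shape}")
        t_emb = self.time(t)
        h = p + zt
        if self.patchify > 1:
            h = h.space_to_depth(self.patchify)
        h = self.conv_in(h)
        skips = []
        for i in range(4):
            h = self.blocks[i](h, t_emb)
            h = self.attn[i](h)
            skips.append(h)
            if i < 3:
                h = self.downs[i](h)
        middle = self.arm_res2(self.arm_sela(self.arm_res1(h, t_emb)), t_emb)
        return ARFeatures(skips=skips, middle=middle)


def denoise_with_ar(zt: Tensor, t, x: Tensor, denoiser, ar_net) -> Tensor:
    """Noise prediction conditioned on the original image via the AR network;
    with ar_net=None this is the plain unconditional denoiser."""
    feats = ar_net(x, zt, t) if ar_net is not None else None
    return denoiser(zt, t, ar=feats)
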