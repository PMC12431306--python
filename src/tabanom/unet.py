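"""U-shaped noise-prediction network.

Four resolution levels with residual blocks, sinusoidal time conditioning
and single-head self-attention at the deepest level.  The decoder accepts
optional assisted-reconstruction (AR) conditioning: a middle feature added
to the mid-block activation and per-scale features concatenated into the
decoder skip connections.  When AR is disabled the model is a plain
unconditional denoiser.

``patchify`` > 1 packs r x r pixel blocks into channels before the first
convolution and unpacks at the output, so the whole U runs at 1/r the
spatial resolution — a lossless rearrangement that trades channel width for
CPU-friendly spatial sizes at desk scale.
"""

from __future__ import annotations

import numpy as np

from .blocks import ResBlock, SelfAttention2d, TimeMLP
from .nn import Conv2d, GroupNorm, Identity, Module, ModuleList, Tensor, concat

__all__ = ["UNetDenoiser"]


class UNetDenoiser(Module):
    def __init__(self, in_channels: int = 3, widths=(64, 128, 192, 256),
                 ar_widths=(0, 0, 0, 0), attn_levels=(3,), patchify: int = 1,
                 seed: int = 0, dtype=np.float32):
        if len(widths) != 4 or len(ar_widths) != 4:
            raise ValueError("widths and ar_widths must have 4 levels")
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.ar_widths = tuple(ar_widths)
        self.attn_levels = tuple(attn_levels)
        self.patchify = patchify
        packed = in_channels * patchify * patchify
        t_dim = 4 * widths[0]
        self.time = TimeMLP(t_dim, rng, dtype=dtype)
        self.conv_in = Conv2d(packed, widths[0], 3, rng, padding=1, dtype=dtype)

        self.down_res = ModuleList(
            ResBlock(widths[i], widths[i], t_dim, rng, dtype=dtype) for i in range(4))
        self.down_attn = ModuleList(
            SelfAttention2d(widths[i], rng, dtype=dtype) if i in attn_levels else Identity()
            for i in range(4))
        self.downs = ModuleList(
            Conv2d(widths[i], widths[i + 1], 3, rng, stride=2, padding=1, dtype=dtype)
            for i in range(3))

        self.mid1 = ResBlock(widths[3], widths[3], t_dim, rng, dtype=dtype)
        self.mid_attn = SelfAttention2d(widths[3], rng, dtype=dtype)
        self.mid2 = ResBlock(widths[3], widths[3], t_dim, rng, dtype=dtype)

        self.up_res = ModuleList(
            ResBlock(widths[i] + widths[i] + ar_widths[i], widths[i], t_dim, rng, dtype=dtype)
            for i in range(4))
        self.ups = ModuleList(
            Conv2d(widths[i + 1], widths[i], 3, rng, padding=1, dtype=dtype)
            for i in range(3))

        self.out_norm = GroupNorm(widths[0], dtype=dtype)
        self.out_conv = Conv2d(widths[0], packed, 3, rng, padding=1, dtype=dtype)
        self.out_conv.w.data[...] = 0.0   # zero noise prediction at init

    def forward(self, zt: Tensor, t, ar=None) -> Tensor:
        """Predict the injected noise for zt at steps t (per-sample ints).

        ``ar`` is an object with ``skips`` (4 feature maps, full->deep) and
        ``middle`` (deepest-resolution map), or None.
        """
        t_emb = self.time(t)
        if self.patchify > 1:
            zt = zt.space_to_depth(self.patchify)
        h = self.conv_in(zt)
        skips = []
        for i in range(4):
            h = self.down_res[i](h, t_emb)
            h = self.down_attn[i](h)
            skips.append(h)
            if i < 3:
                h = self.downs[i](h)

        h = self.mid1(h, t_emb)
        if ar is not None:
            mid = ar.middle
            if mid.shape != h.shape:
                raise ValueError(
                    f"AR middle feature shape {mid.shape} does not match mid block {h.shape}")
            h = h + mid
        h = self.mid_attn(h)
        h = self.mid2(h, t_emb)

        for i in range(3, -1, -1):
            parts = [h, skips[i]]
            if ar is not None and self.ar_widths[i]:
                s = ar.skips[i]
                if s.shape[2:] != h.shape[2:] or s.shape[1] != self.ar_widths[i]:
                    raise ValueError(
                        f"AR skip at level {i} has shape {s.shape}, expected "
                        f"({h.shape[0]}, {self.ar_widths[i]}, {h.shape[2]}, {h.shape[3]})")
                parts.append(s)
            h = self.up_res[i](concat(parts, axis=1), t_emb)
            if i > 0:
                h = self.ups[i - 1](h.upsample_nearest(2))
        out = self.out_conv(self.out_norm(h).silu())
        if self.patchify > 1:
            out = out.depth_to_space(self.patchify)
        return out
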