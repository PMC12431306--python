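"""Layer abstractions over the autograd engine.

Mirrors the familiar Module/parameter idiom: a :class:`Module` owns
parameters and sub-modules discovered by attribute traversal, supports
``state_dict``/``load_state_dict`` round-trips through ``.npz`` files, and
is called like a function.  Weight initialisation is explicit — every layer
takes a ``numpy.random.Generator`` so whole networks are reproducible from
one seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module", "Sequential", "ModuleList", "Identity",
    "Conv2d", "Linear", "GroupNorm", "ChannelLayerNorm",
]


class Module:
    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as z:
            self.load_state_dict({k: z[k] for k in z.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = ModuleList(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        self._items = list(mods)

    def append(self, m: Module):
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._items):
            yield from m.named_parameters(f"{prefix}{i}.")


def _param(rng: np.random.Generator, shape, fan_in: int, dtype) -> Tensor:
    # He-style uniform keeps activations in range for ReLU-family nets.
    bound = float(np.sqrt(1.0 / max(fan_in, 1)))
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(dtype),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 groups: int = 1, bias: bool = True, dtype=np.float32):
        if c_in % groups or c_out % groups:
            raise ValueError(f"channels ({c_in}->{c_out}) not divisible by groups={groups}")
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = (c_in // groups) * k * k
        self.w = _param(rng, (c_out, c_in // groups, k, k), fan_in, dtype)
        self.b = _param(rng, (c_out,), fan_in, dtype) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.w, self.b, stride=self.stride, padding=self.padding,
                        dilation=self.dilation, groups=self.groups)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float32):
        self.w = _param(rng, (n_in, n_out), n_in, dtype)
        self.b = _param(rng, (n_out,), n_in, dtype) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y


class GroupNorm(Module):
    """Normalise NCHW activations over (channel-group, H, W)."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5,
                 dtype=np.float32):
        while channels % groups:
            groups //= 2
        self.groups, self.eps = max(groups, 1), eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.group_norm(self.gamma, self.beta, self.groups, self.eps)


class ChannelLayerNorm(Module):
    """Layer normalisation over the channel axis at each spatial position."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.channel_layer_norm(self.gamma, self.beta, self.eps)
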