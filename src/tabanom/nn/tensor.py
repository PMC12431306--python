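"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray``, records
the operations applied to it, and :meth:`Tensor.backward` accumulates
gradients by walking the tape in reverse topological order.  Only the
operations the networks in this package need are provided (dense and
convolutional linear maps, the usual activations, reductions, reshapes,
pooling and nearest-neighbour upsampling).  All operations support
broadcasting the way numpy does; gradients of broadcast operands are summed
back to the operand's shape.

Arrays are NCHW for image-like data.  The engine is dtype-preserving:
float32 graphs stay float32 (training speed), float64 graphs stay float64
(finite-difference checks).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._prev = _prev
        self.name = None

    # ------------------------------------------------------------------ util
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------ graph core
    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req,
                     _prev=tuple(p for p in parents if p.requires_grad) if req else ())
        if req:
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    @staticmethod
    def _coerce(other, like: "Tensor") -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=like.data.dtype))

    def __add__(self, other):
        other = self._coerce(other, self)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(g)
            if b.requires_grad:
                b._accum(g)

        return Tensor._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._result(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._coerce(other, self))

    def __rsub__(self, other):
        return self._coerce(other, self) + (-self)

    def __mul__(self, other):
        other = self._coerce(other, self)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(g * b.data)
            if b.requires_grad:
                b._accum(g * a.data)

        return Tensor._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other, self)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other, self) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        a = self
        out_data = a.data ** p

        def bw(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._result(out_data, (a,), bw)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def square(self) -> "Tensor":
        return self * self

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return Tensor._result(out_data, (a,), bw)

    def log(self) -> "Tensor":
        a = self

        def bw(g):
            a._accum(g / a.data)

        return Tensor._result(np.log(a.data), (a,), bw)

    def __matmul__(self, other):
        other = self._coerce(other, self)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(np.matmul(g, np.swapaxes(b.data, -1, -2)))
            if b.requires_grad:
                b._accum(np.matmul(np.swapaxes(a.data, -1, -2), g))

        return Tensor._result(np.matmul(a.data, b.data), (a, b), bw)

    # ------------------------------------------------------------ activations
    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return Tensor._result(a.data * mask, (a,), bw)

    def sigmoid(self) -> "Tensor":
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (a,), bw)

    def tanh(self) -> "Tensor":
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - out_data * out_data))

        return Tensor._result(out_data, (a,), bw)

    def silu(self) -> "Tensor":
        a = self
        sig = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * (sig + a.data * sig * (1.0 - sig)))

        return Tensor._result(a.data * sig, (a,), bw)

    def gelu(self) -> "Tensor":
        """Exact Gaussian-error-linear unit, 0.5 x (1 + erf(x/sqrt(2)))."""
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def bw(g):
            a._accum(g * (cdf + x * pdf))

        return Tensor._result((x * cdf).astype(x.dtype), (a,), bw)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape))

        return Tensor._result(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_spatial(self) -> "Tensor":
        """Max over the two trailing (spatial) axes, keepdims. NCHW only."""
        a = self
        N, C, H, W = a.data.shape
        flat = a.data.reshape(N, C, H * W)
        idx = flat.argmax(axis=2)
        out_data = np.take_along_axis(flat, idx[:, :, None], axis=2).reshape(N, C, 1, 1)

        def bw(g):
            gf = np.zeros_like(flat)
            np.put_along_axis(gf, idx[:, :, None], g.reshape(N, C, 1), axis=2)
            a._accum(gf.reshape(a.data.shape))

        return Tensor._result(out_data, (a,), bw)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # ------------------------------------------------------------- structure
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bw(g):
            a._accum(g.reshape(orig))

        return Tensor._result(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))

        return Tensor._result(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, key) -> "Tensor":
        a = self

        def bw(g):
            buf = np.zeros_like(a.data)
            buf[key] = g
            a._accum(buf)

        return Tensor._result(a.data[key], (a,), bw)

    def pad2d(self, p: int) -> "Tensor":
        if p == 0:
            return self
        a = self

        def bw(g):
            a._accum(g[:, :, p:-p, p:-p])

        return Tensor._result(
            np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p))), (a,), bw)

    # ------------------------------------------------------- fused normalizers
    def group_norm(self, gamma: "Tensor", beta: "Tensor", groups: int,
                   eps: float = 1e-5) -> "Tensor":
        """Fused group normalisation over (channel-group, H, W), NCHW."""
        a = self
        x = a.data
        N, C, H, W = x.shape
        g = groups
        xg = x.reshape(N, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = ((xg - mu) * inv).reshape(N, C, H, W)
        out_data = xhat * gamma.data + beta.data

        def bw(gr):
            if gamma.requires_grad:
                gamma._accum((gr * xhat).sum(axis=(0, 2, 3)).reshape(gamma.data.shape))
            if beta.requires_grad:
                beta._accum(gr.sum(axis=(0, 2, 3)).reshape(beta.data.shape))
            if a.requires_grad:
                dxhat = (gr * gamma.data).reshape(N, g, -1)
                xh = xhat.reshape(N, g, -1)
                m1 = dxhat.mean(axis=2, keepdims=True)
                m2 = (dxhat * xh).mean(axis=2, keepdims=True)
                a._accum(((dxhat - m1 - xh * m2) * inv).reshape(x.shape))

        return Tensor._result(out_data, (a, gamma, beta), bw)

    def channel_layer_norm(self, gamma: "Tensor", beta: "Tensor",
                           eps: float = 1e-5) -> "Tensor":
        """Fused layer norm over the channel axis per spatial position."""
        a = self
        x = a.data
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out_data = xhat * gamma.data + beta.data
        C = x.shape[1]

        def bw(gr):
            if gamma.requires_grad:
                gamma._accum((gr * xhat).sum(axis=(0, 2, 3)).reshape(gamma.data.shape))
            if beta.requires_grad:
                beta._accum(gr.sum(axis=(0, 2, 3)).reshape(beta.data.shape))
            if a.requires_grad:
                dxhat = gr * gamma.data
                m1 = dxhat.mean(axis=1, keepdims=True)
                m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
                a._accum((dxhat - m1 - xhat * m2) * inv)

        return Tensor._result(out_data, (a, gamma, beta), bw)

    # ----------------------------------------------------------- rearrangement
    def space_to_depth(self, r: int) -> "Tensor":
        """(N,C,H,W) -> (N, C*r*r, H/r, W/r) by packing r x r pixel blocks."""
        a = self
        N, C, H, W = a.data.shape
        if H % r or W % r:
            raise ValueError(f"spatial dims {H}x{W} not divisible by {r}")
        out_data = a.data.reshape(N, C, H // r, r, W // r, r) \
                         .transpose(0, 1, 3, 5, 2, 4) \
                         .reshape(N, C * r * r, H // r, W // r)

        def bw(g):
            a._accum(g.reshape(N, C, r, r, H // r, W // r)
                     .transpose(0, 1, 4, 2, 5, 3).reshape(N, C, H, W))

        return Tensor._result(np.ascontiguousarray(out_data), (a,), bw)

    def depth_to_space(self, r: int) -> "Tensor":
        """(N, C*r*r, H, W) -> (N, C, H*r, W*r); inverse of space_to_depth."""
        a = self
        N, Crr, H, W = a.data.shape
        C = Crr // (r * r)
        out_data = a.data.reshape(N, C, r, r, H, W) \
                         .transpose(0, 1, 4, 2, 5, 3) \
                         .reshape(N, C, H * r, W * r)

        def bw(g):
            a._accum(g.reshape(N, C, H, r, W, r)
                     .transpose(0, 1, 3, 5, 2, 4).reshape(N, Crr, H, W))

        return Tensor._result(np.ascontiguousarray(out_data), (a,), bw)

    # ---------------------------------------------------------- conv/pooling
    def conv2d(self, w: "Tensor", b: "Tensor" | None = None, stride: int = 1,
               padding: int = 0, dilation: int = 1, groups: int = 1) -> "Tensor":
        """2-D cross-correlation, NCHW, grouped/dilated/strided."""
        a = self
        x = a.data
        N, C, H, W = x.shape
        Cout, Cg, KH, KW = w.data.shape
        G = groups
        if C != Cg * G or Cout % G:
            raise ValueError(
                f"conv2d channel mismatch: input {C}, weight {w.data.shape}, groups {G}")
        if KH == 1 and KW == 1 and stride == 1 and padding == 0:
            return self._conv1x1(w, b, groups)
        eKH = (KH - 1) * dilation + 1
        eKW = (KW - 1) * dilation + 1
        OH = (H + 2 * padding - eKH) // stride + 1
        OW = (W + 2 * padding - eKW) // stride + 1
        if OH <= 0 or OW <= 0:
            raise ValueError("conv2d output would be empty")
        y, cols_m = _conv_raw(x, w.data, stride, padding, dilation, G)
        if b is not None:
            y += b.data.reshape(1, Cout, 1, 1)

        parents = (a, w) if b is None else (a, w, b)
        Cog = Cout // G

        def bw(g):
            gy = g.reshape(N, G, Cog, OH, OW).transpose(1, 0, 3, 4, 2) \
                  .reshape(G, N * OH * OW, Cog)
            if w.requires_grad:
                dw = np.matmul(np.swapaxes(gy, 1, 2), cols_m)
                w._accum(dw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if a.requires_grad:
                if stride == 1 and eKH - 1 >= padding and eKW - 1 >= padding:
                    # dx is itself a stride-1 correlation of the output
                    # gradient with flipped kernels, input/output swapped
                    wt = np.ascontiguousarray(
                        w.data.reshape(G, Cog, Cg, KH, KW)
                              .transpose(0, 2, 1, 3, 4)
                              .reshape(C, Cog, KH, KW)[:, :, ::-1, ::-1])
                    dx, _ = _conv_raw(np.ascontiguousarray(g), wt, 1,
                                      eKH - 1 - padding, dilation, G,
                                      need_cols=False)
                    a._accum(dx)
                else:
                    w_m = w.data.reshape(G, Cog, Cg * KH * KW)
                    dcols = np.matmul(gy, w_m)     # (G, N*OH*OW, Cg*KH*KW)
                    dcols = dcols.reshape(G, N, OH, OW, Cg, KH, KW) \
                                 .transpose(1, 0, 4, 5, 6, 2, 3) \
                                 .reshape(N, C, KH, KW, OH, OW)
                    dxp = np.zeros((N, C, H + 2 * padding, W + 2 * padding),
                                   dtype=x.dtype)
                    for i in range(KH):
                        hi = i * dilation
                        for j in range(KW):
                            wj = j * dilation
                            dxp[:, :, hi:hi + (OH - 1) * stride + 1:stride,
                                wj:wj + (OW - 1) * stride + 1:stride] \
                                += dcols[:, :, i, j]
                    a._accum(dxp[:, :, padding:padding + H, padding:padding + W]
                             if padding else dxp)

        return Tensor._result(y, parents, bw)

    def _conv1x1(self, w: "Tensor", b: "Tensor" | None, groups: int) -> "Tensor":
        """Pointwise convolution as a channel matmul (no im2col)."""
        a = self
        x = a.data
        N, C, H, W = x.shape
        Cout = w.data.shape[0]
        G = groups
        Cg, Cog = C // G, Cout // G
        xm = x.reshape(N, G, Cg, H * W)
        wm = w.data.reshape(G, Cog, Cg)
        y = np.matmul(wm[None], xm)                 # (N, G, Cog, H*W)
        y = y.reshape(N, Cout, H, W)
        if b is not None:
            y += b.data.reshape(1, Cout, 1, 1)
        parents = (a, w) if b is None else (a, w, b)

        def bw(g):
            gm = g.reshape(N, G, Cog, H * W)
            if w.requires_grad:
                dw = np.einsum("ngop,ngcp->goc", gm, xm, optimize=True)
                w._accum(dw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if a.requires_grad:
                dx = np.matmul(np.swapaxes(wm, 1, 2)[None], gm)
                a._accum(dx.reshape(x.shape))

        return Tensor._result(y, parents, bw)

    def avg_pool2d(self, k: int = 2) -> "Tensor":
        a = self
        N, C, H, W = a.data.shape
        if H % k or W % k:
            raise ValueError(f"avg_pool2d: {H}x{W} not divisible by {k}")
        out_data = a.data.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))

        def bw(g):
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            a._accum(gx.astype(a.data.dtype))

        return Tensor._result(out_data, (a,), bw)

    def upsample_nearest(self, scale: int = 2) -> "Tensor":
        a = self
        out_data = np.repeat(np.repeat(a.data, scale, axis=2), scale, axis=3)

        def bw(g):
            N, C, H, W = a.data.shape
            a._accum(g.reshape(N, C, H, scale, W, scale).sum(axis=(3, 5)))

        return Tensor._result(out_data, (a,), bw)


def _conv_raw(x: np.ndarray, wdata: np.ndarray, stride: int, padding: int,
              dilation: int, G: int, need_cols: bool = True):
    """Grouped 2-D cross-correlation on plain arrays via strided im2col.

    Returns (y, cols_m); ``cols_m`` is the im2col matrix reused for the
    weight gradient, or None when ``need_cols`` is False.
    """
    N, C, H, W = x.shape
    Cout, Cg, KH, KW = wdata.shape
    Cog = Cout // G
    eKH = (KH - 1) * dilation + 1
    eKW = (KW - 1) * dilation + 1
    OH = (H + 2 * padding - eKH) // stride + 1
    OW = (W + 2 * padding - eKW) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(N, C, KH, KW, OH, OW),
        strides=(s[0], s[1], s[2] * dilation, s[3] * dilation,
                 s[2] * stride, s[3] * stride),
        writeable=False,
    )
    cols_m = cols.reshape(N, G, Cg, KH, KW, OH, OW) \
                 .transpose(1, 0, 5, 6, 2, 3, 4) \
                 .reshape(G, N * OH * OW, Cg * KH * KW)
    w_m = wdata.reshape(G, Cog, Cg * KH * KW)
    y = np.matmul(cols_m, np.swapaxes(w_m, 1, 2))      # (G, N*OH*OW, Cog)
    y = y.reshape(G, N, OH, OW, Cog).transpose(1, 0, 4, 2, 3) \
         .reshape(N, Cout, OH, OW)
    return y, (cols_m if need_cols else None)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._result(out_data, tuple(tensors), bw)
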