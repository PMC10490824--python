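"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The detector in this package is small enough to train on a CPU, so instead of a
heavyweight deep-learning framework it runs on this engine: a :class:`Tensor`
wrapping a float32 ``ndarray`` plus the handful of differentiable primitives a
convolutional detector needs (convolution, pooling, elementwise math, indexing,
concatenation).  Gradients are accumulated by topological-order backpropagation.

Design constraints:

* float32 everywhere; gradients share dtype with data.
* Broadcasting follows NumPy rules; gradients are summed back to input shapes.
* Graph construction can be switched off globally (:func:`no_grad`) for
  inference, which keeps large forward passes memory-flat.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A float32 array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, pow_(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), pow_(self, -1.0))

    def __pow__(self, exponent):
        return pow_(self, exponent)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # ----------------------------------------------------------- conveniences
    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(out_data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(out_data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ------------------------------------------------------------------ primitives
def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def pow_(a, exponent: float) -> Tensor:
    a = _wrap(a)
    e = float(exponent)
    out_data = a.data**e

    def backward(g):
        a._accumulate(g * e * a.data ** (e - 1.0))

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return pow_(a, 0.5)


def _sigmoid_stable(x: np.ndarray) -> np.ndarray:
    # clip at 60: sigmoid saturates well past float32 resolution there
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out_data = _sigmoid_stable(a.data)

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def silu(a) -> Tensor:
    """x * sigmoid(x) — the activation used throughout the conv blocks."""
    a = _wrap(a)
    s = _sigmoid_stable(a.data)
    out_data = a.data * s

    def backward(g):
        a._accumulate(g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(out_data, (a,), backward)


def hardswish(a) -> Tensor:
    """x * relu6(x + 3) / 6 (coordinate-attention convention)."""
    a = _wrap(a)
    x = a.data
    inner = np.clip(x + 3.0, 0.0, 6.0)
    out_data = x * inner / 6.0

    def backward(g):
        d = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
        a._accumulate(g * d.astype(np.float32))

    return _make(out_data, (a,), backward)


def softplus(a) -> Tensor:
    """log(1 + exp(x)), numerically stable; derivative sigmoid(x)."""
    a = _wrap(a)
    out_data = np.logaddexp(0.0, a.data).astype(np.float32)

    def backward(g):
        a._accumulate(g * _sigmoid_stable(a.data))

    return _make(out_data, (a,), backward)


def atan(a) -> Tensor:
    a = _wrap(a)
    out_data = np.arctan(a.data)

    def backward(g):
        a._accumulate(g / (1.0 + a.data * a.data))

    return _make(out_data, (a,), backward)


def clamp(a, lo: float | None = None, hi: float | None = None) -> Tensor:
    a = _wrap(a)
    out_data = np.clip(a.data, lo, hi)
    pass_mask = np.ones_like(a.data)
    if lo is not None:
        pass_mask *= a.data >= lo
    if hi is not None:
        pass_mask *= a.data <= hi

    def backward(g):
        a._accumulate(g * pass_mask)

    return _make(out_data, (a,), backward)


def maximum(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = np.maximum(a.data, b.data)
    a_wins = (a.data > b.data).astype(np.float32)
    tie = (a.data == b.data).astype(np.float32) * 0.5

    def backward(g):
        a._accumulate(_unbroadcast(g * (a_wins + tie), a.data.shape))
        b._accumulate(_unbroadcast(g * (1.0 - a_wins - tie), b.data.shape))

    return _make(out_data, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = np.minimum(a.data, b.data)
    a_wins = (a.data < b.data).astype(np.float32)
    tie = (a.data == b.data).astype(np.float32) * 0.5

    def backward(g):
        a._accumulate(_unbroadcast(g * (a_wins + tie), a.data.shape))
        b._accumulate(_unbroadcast(g * (1.0 - a_wins - tie), b.data.shape))

    return _make(out_data, (a, b), backward)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))
            return
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        if not keepdims:
            g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return _make(out_data, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(np.transpose(g, inv))

    return _make(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = _wrap(a)
    out_data = a.data[idx]
    if out_data.base is not None:
        out_data = out_data.copy()

    def backward(g):
        buf = np.zeros_like(a.data)
        np.add.at(buf, idx, g)
        a._accumulate(buf)

    return _make(out_data, (a,), backward)


def cat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(lo), int(hi))
            t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(ts), backward)


def pad2d(a, pad: int, value: float = 0.0) -> Tensor:
    """Pad the two trailing spatial axes of an NCHW tensor."""
    a = _wrap(a)
    if pad == 0:
        return a
    out_data = np.pad(
        a.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=value
    )

    def backward(g):
        a._accumulate(g[:, :, pad:-pad, pad:-pad])

    return _make(out_data, (a,), backward)


# --------------------------------------------------------------- convolutions
def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW / OIHW layout.

    Implemented as a sum of strided GEMMs over kernel offsets, which keeps
    memory flat (no im2col buffer) while staying BLAS-bound.
    """
    x, weight = _wrap(x), _wrap(weight)
    xd, wd = x.data, weight.data
    n, c, h, w = xd.shape
    o, cg, kh, kw = wd.shape
    if c != cg * groups:
        raise ValueError(f"channel mismatch: input {c}, weights expect {cg * groups}")
    s, p = int(stride), int(padding)
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // s + 1
    wo = (wp - kw) // s + 1
    og = o // groups
    out_data = np.zeros((n, o, ho, wo), dtype=np.float32)
    for g_idx in range(groups):
        xg = xp[:, g_idx * cg:(g_idx + 1) * cg]
        wg = wd[g_idx * og:(g_idx + 1) * og]
        acc = out_data[:, g_idx * og:(g_idx + 1) * og]
        for i in range(kh):
            for j in range(kw):
                xs = xg[:, :, i:i + s * (ho - 1) + 1:s, j:j + s * (wo - 1) + 1:s]
                acc += np.tensordot(xs, wg[:, :, i, j], axes=([1], [1])).transpose(
                    0, 3, 1, 2
                )

    def backward(g_out):
        gw = np.zeros_like(wd)
        gxp = np.zeros_like(xp)
        for g_idx in range(groups):
            xg = xp[:, g_idx * cg:(g_idx + 1) * cg]
            wg = wd[g_idx * og:(g_idx + 1) * og]
            gog = g_out[:, g_idx * og:(g_idx + 1) * og]
            gxg = gxp[:, g_idx * cg:(g_idx + 1) * cg]
            for i in range(kh):
                for j in range(kw):
                    sl_h = slice(i, i + s * (ho - 1) + 1, s)
                    sl_w = slice(j, j + s * (wo - 1) + 1, s)
                    xs = xg[:, :, sl_h, sl_w]
                    gw[g_idx * og:(g_idx + 1) * og, :, i, j] += np.tensordot(
                        gog, xs, axes=([0, 2, 3], [0, 2, 3])
                    )
                    gxg[:, :, sl_h, sl_w] += np.tensordot(
                        gog, wg[:, :, i, j], axes=([1], [0])
                    ).transpose(0, 3, 1, 2)
        weight._accumulate(gw)
        x._accumulate(gxp[:, :, p:p + h, p:p + w] if p else gxp)

    out = _make(out_data, (x, weight), backward)
    if bias is not None:
        out = add(out, reshape(bias, (1, -1, 1, 1)))
    return out


def maxpool2d(x, kernel: int, stride: int, padding: int = 0) -> Tensor:
    x = _wrap(x)
    xd = x.data
    n, c, h, w = xd.shape
    k, s, p = int(kernel), int(stride), int(padding)
    xp = (
        np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        if p
        else xd
    )
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - k) // s + 1
    wo = (wp - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::s, ::s][:, :, :ho, :wo].reshape(n, c, ho, wo, k * k)
    arg = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gxp = np.zeros_like(xp)
        ni, ci, yi, xi = np.indices((n, c, ho, wo), sparse=False)
        rows = yi * s + arg // k
        cols = xi * s + arg % k
        flat = ((ni * c + ci) * hp + rows) * wp + cols
        np.add.at(gxp.ravel(), flat.ravel(), g.ravel())
        x._accumulate(gxp[:, :, p:p + h, p:p + w] if p else gxp)

    return _make(out_data, (x,), backward)


def upsample_nearest2x(x) -> Tensor:
    x = _wrap(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        x._accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward)


def unfold3x3(x) -> Tensor:
    """Gather each 3x3 neighborhood: (N,C,H,W) -> (N,C,9,H,W), zero-padded.

    Offset order is row-major over (dy,dx) in {-1,0,1}^2.
    """
    x = _wrap(x)
    xd = x.data
    n, c, h, w = xd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out_data = np.empty((n, c, 9, h, w), dtype=np.float32)
    for t, (dy, dx) in enumerate((dy, dx) for dy in range(3) for dx in range(3)):
        out_data[:, :, t] = xp[:, :, dy:dy + h, dx:dx + w]

    def backward(g):
        gxp = np.zeros_like(xp)
        for t, (dy, dx) in enumerate((dy, dx) for dy in range(3) for dx in range(3)):
            gxp[:, :, dy:dy + h, dx:dx + w] += g[:, :, t]
        x._accumulate(gxp[:, :, 1:-1, 1:-1])

    return _make(out_data, (x,), backward)
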