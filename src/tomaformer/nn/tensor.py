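"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations that
produced it; calling :meth:`Tensor.backward` on a scalar loss walks the
tape in reverse topological order and accumulates vector-Jacobian
products into ``.grad``. Only the primitives needed by the segmentation
network are provided: broadcasting arithmetic, matmul, shape ops,
elementwise nonlinearities, reductions, 2-D convolution, 2x2 max
pooling/unpooling, and bilinear resampling.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autodiff engine ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64)
    else:
        t.grad = t.grad + g


# -- primitives ---------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** exponent

    def backward(g):
        _accum(a, g * exponent * a.data ** (exponent - 1.0))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        _accum(a, g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        _accum(a, g * mask)

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _accum(a, _unbroadcast(ga, a.data.shape))
        _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    orig = a.data.shape
    data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(orig))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(data, tuple(tensors), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max shift is gradient-free, which is
    exact because the softmax Jacobian annihilates constant shifts."""
    a = _as_tensor(a)
    shifted = a - Tensor(a.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return e / tsum(e, axis=axis, keepdims=True)


# -- spatial primitives (NCHW layout) -----------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW x OIHW."""
    x, w = _as_tensor(x), _as_tensor(w)
    n, cin, h, wd = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh, ow = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (n, cin, oh, ow, kh, kw) -> col: (n*oh*ow, cin*kh*kw)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, cin * kh * kw)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = col @ wmat.T
    if b is not None:
        out = out + b.data
    data = out.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)

    def backward(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, cout)
        gw = (g2.T @ col).reshape(cout, cin, kh, kw)
        _accum(w, gw)
        if b is not None:
            _accum(b, g2.sum(axis=0))
        gcol = (g2 @ wmat).reshape(n, oh, ow, cin, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + oh, j:j + ow] += gcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        _accum(x, gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


def max_pool2x2(x: Tensor) -> tuple[Tensor, np.ndarray]:
    """2x2 stride-2 max pooling; returns (pooled, argmax) where argmax holds
    the within-window winner index in {0,1,2,3} (row-major) per output cell."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    oh, ow = h // 2, w // 2
    windows = x.data.reshape(n, c, oh, 2, ow, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, 4)
    idx = windows.argmax(axis=-1)
    data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros((n, c, oh, ow, 4))
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = gw.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        _accum(x, gx)

    return _make(data, (x,), backward), idx


def max_unpool2x2(x: Tensor, idx: np.ndarray) -> Tensor:
    """Place each value at its recorded argmax coordinate; zeros elsewhere."""
    x = _as_tensor(x)
    n, c, oh, ow = x.data.shape
    if idx.shape != (n, c, oh, ow):
        raise ValueError("argmax indices do not match input shape")
    windows = np.zeros((n, c, oh, ow, 4))
    np.put_along_axis(windows, idx[..., None], x.data[..., None], axis=-1)
    data = windows.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh * 2, ow * 2)

    def backward(g):
        gw = g.reshape(n, c, oh, 2, ow, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, 4)
        _accum(x, np.take_along_axis(gw, idx[..., None], axis=-1)[..., 0])

    return _make(data, (x,), backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1 - frac
    m[np.arange(n_out), hi] += frac
    return m


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resampling of an NCHW tensor to ``out_hw``."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    oh, ow = out_hw
    ar = _interp_matrix(oh, h)
    ac = _interp_matrix(ow, w)
    data = np.einsum("rh,nchw,sw->ncrs", ar, x.data, ac, optimize=True)

    def backward(g):
        _accum(x, np.einsum("rh,ncrs,sw->nchw", ar, g, ac, optimize=True))

    return _make(data, (x,), backward)
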