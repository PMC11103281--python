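"""Compact reverse-mode automatic differentiation over numpy arrays.

The translation networks in this package are small encoder--decoder CNNs
trained at desk scale on CPU.  This module provides the minimal tensor
algebra they need: broadcast arithmetic, matrix products, N-dimensional
strided convolutions and their transposes (via im2col / col2im), instance
normalisation, dropout, and the stabilised log-sigmoid primitives used by
the adversarial losses.  Everything is float64 and operates on un-batched
arrays shaped ``(channels, *spatial)`` -- minibatch size is one throughout
the training procedure, so no batch axis is carried.

Gradients are accumulated by a topological-order sweep of the operation
graph, in the style of micrograd but vectorised.  A module-level
``no_grad()`` context disables graph construction for inference.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """An array node in the differentiation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may be a view into a buffer the caller reuses
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Reverse sweep seeding d(self)/d(self) = 1.

        The graph is dismantled afterwards: each node's closure refers back
        to the node, and those reference cycles hold large array buffers
        that garbage collection reclaims too slowly during training.
        """
        topo = _toposort(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        for node in topo:
            node._backward = None
            node._parents = ()

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division is not supported")
        return mul(self, 1.0 / float(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self):
        return tsum(self)

    def mean(self):
        return tmean(self)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    state: dict[int, int] = {}
    stack: list[Tensor] = [root]
    while stack:
        node = stack[-1]
        st = state.get(id(node), 0)
        if st == 0:
            state[id(node)] = 1
            for p in node._parents:
                if state.get(id(p), 0) == 0:
                    stack.append(p)
        else:
            stack.pop()
            if st == 1:
                state[id(node)] = 2
                order.append(node)
    return order


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _tracked(*parents: Tensor) -> bool:
    return _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _tracked(*parents):
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise and reduction ops ------------------------------------------


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward():
        if out.grad is None:
            return
        a._accumulate(_unbroadcast(out.grad, a.data.shape))
        b._accumulate(_unbroadcast(out.grad, b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward():
        a._accumulate(_unbroadcast(out.grad * b.data, a.data.shape))
        b._accumulate(_unbroadcast(out.grad * a.data, b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def absolute(a: Tensor) -> Tensor:
    a = _wrap(a)
    sign = np.sign(a.data)

    def backward():
        a._accumulate(out.grad * sign)

    out = _make(np.abs(a.data), (a,), backward)
    return out


def tsum(a: Tensor) -> Tensor:
    a = _wrap(a)

    def backward():
        a._accumulate(np.full_like(a.data, float(out.grad)))

    out = _make(np.asarray(a.data.sum()), (a,), backward)
    return out


def tmean(a: Tensor) -> Tensor:
    a = _wrap(a)
    n = a.data.size

    def backward():
        a._accumulate(np.full_like(a.data, float(out.grad) / n))

    out = _make(np.asarray(a.data.mean()), (a,), backward)
    return out


def reshape(a: Tensor, shape) -> Tensor:
    a = _wrap(a)
    old = a.data.shape

    def backward():
        a._accumulate(out.grad.reshape(old))

    out = _make(a.data.reshape(shape), (a,), backward)
    return out


def _is_basic_index(idx) -> bool:
    parts = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(p, (int, slice, type(Ellipsis), type(None))) for p in parts)


def getitem(a: Tensor, idx) -> Tensor:
    a = _wrap(a)

    def backward():
        g = np.zeros_like(a.data)
        if _is_basic_index(idx):
            g[idx] += out.grad
        else:
            np.add.at(g, idx, out.grad)
        a._accumulate(g)

    out = _make(a.data[idx], (a,), backward)
    return out


def pad(a: Tensor, pad_width) -> Tensor:
    """Zero padding; ``pad_width`` as for ``np.pad``."""
    a = _wrap(a)
    pw = tuple((int(l), int(r)) for l, r in pad_width)

    def backward():
        core = tuple(slice(l, g - r) for (l, r), g in zip(pw, out.grad.shape))
        a._accumulate(out.grad[core])

    out = _make(np.pad(a.data, pw), (a,), backward)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward():
        parts = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, parts):
            t._accumulate(g)

    out = _make(np.concatenate([t.data for t in tensors], axis=axis),
                tuple(tensors), backward)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward():
        a._accumulate(out.grad @ b.data.T)
        b._accumulate(a.data.T @ out.grad)

    out = _make(a.data @ b.data, (a, b), backward)
    return out


# -- nonlinearities ----------------------------------------------------------


def sigmoid(a: Tensor) -> Tensor:
    a = _wrap(a)
    y = np.empty_like(a.data)
    pos = a.data >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    y[~pos] = ex / (1.0 + ex)

    def backward():
        a._accumulate(out.grad * y * (1.0 - y))

    out = _make(y, (a,), backward)
    return out


def softplus(a: Tensor) -> Tensor:
    """ln(1 + e^x), computed stably; finite for every finite logit."""
    a = _wrap(a)
    y = np.logaddexp(0.0, a.data)

    def backward():
        s = np.empty_like(a.data)
        pos = a.data >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
        ex = np.exp(a.data[~pos])
        s[~pos] = ex / (1.0 + ex)
        a._accumulate(out.grad * s)

    out = _make(y, (a,), backward)
    return out


def log(a: Tensor) -> Tensor:
    a = _wrap(a)

    def backward():
        a._accumulate(out.grad / a.data)

    out = _make(np.log(a.data), (a,), backward)
    return out


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    a = _wrap(a)
    slope = np.where(a.data > 0, 1.0, alpha)

    def backward():
        a._accumulate(out.grad * slope)

    out = _make(a.data * slope, (a,), backward)
    return out


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


def instance_norm(a: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel standardisation over spatial axes; no learnable affine."""
    a = _wrap(a)
    axes = tuple(range(1, a.data.ndim))
    mu = a.data.mean(axis=axes, keepdims=True)
    var = a.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (a.data - mu) * inv

    def backward():
        g = out.grad
        gm = g.mean(axis=axes, keepdims=True)
        gym = (g * y).mean(axis=axes, keepdims=True)
        a._accumulate(inv * (g - gm - y * gym))

    out = _make(y, (a,), backward)
    return out


def dropout(a: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; active whenever called (training and inference)."""
    a = _wrap(a)
    if p <= 0:
        return a
    mask = (rng.random(a.data.shape) >= p) / (1.0 - p)

    def backward():
        a._accumulate(out.grad * mask)

    out = _make(a.data * mask, (a,), backward)
    return out


# -- convolutions ------------------------------------------------------------


def _im2col(x, k, stride, pad):
    """Column matrix of shape (Ci * prod(k), n_out) plus the out spatial."""
    nd = x.ndim - 1
    xp = np.pad(x, ((0, 0),) + tuple((p, p) for p in pad))
    win = sliding_window_view(xp, k, axis=tuple(range(1, nd + 1)))
    win = win[(slice(None),) + tuple(slice(None, None, s) for s in stride)]
    out_spatial = win.shape[1:1 + nd]
    # (Ci, *out, *k) -> (Ci, *k, n_out) -> (Ci * prod(k), n_out)
    perm = (0,) + tuple(range(1 + nd, 1 + 2 * nd)) + tuple(range(1, 1 + nd))
    cols = np.ascontiguousarray(win.transpose(perm)).reshape(
        x.shape[0] * int(np.prod(k)), -1)
    return cols, out_spatial


def _conv_fwd(x, w, stride, pad, cols=None):
    cols, out_spatial = cols if cols is not None else _im2col(
        x, w.shape[2:], stride, pad)
    out = w.reshape(w.shape[0], -1) @ cols
    return out.reshape((w.shape[0],) + tuple(out_spatial))


def _conv_bwd_w(x, gy, stride, pad, kshape, cols=None):
    if cols is None:
        cols = _im2col(x, kshape[2:], stride, pad)
    gw = gy.reshape(gy.shape[0], -1) @ cols[0].T
    return gw.reshape(kshape)


def _conv_bwd_x(gy, w, stride, pad, xshape):
    """col2im: scatter-add one BLAS product back over kernel offsets."""
    nd = gy.ndim - 1
    k = w.shape[2:]
    ci = xshape[0]
    padded = (ci,) + tuple(xshape[i + 1] + 2 * pad[i] for i in range(nd))
    gxp = np.zeros(padded)
    gyf = gy.reshape(gy.shape[0], -1)
    gcols = w.reshape(w.shape[0], -1).T @ gyf        # (Ci * prod(k), n_out)
    gcols = gcols.reshape((ci,) + tuple(k) + gy.shape[1:])
    for off in np.ndindex(*k):
        sl = (slice(None),) + tuple(
            slice(off[i], off[i] + stride[i] * gy.shape[i + 1], stride[i])
            for i in range(nd)
        )
        gxp[sl] += gcols[(slice(None),) + off]
    core = (slice(None),) + tuple(
        slice(pad[i], pad[i] + xshape[i + 1]) for i in range(nd)
    )
    return gxp[core]


def conv_nd(x: Tensor, w: Tensor, stride: int | Sequence[int] = 1,
            pad: int | Sequence[int] = 0) -> Tensor:
    """Cross-correlation of ``x (Ci, *S)`` with kernels ``w (Co, Ci, *k)``."""
    x, w = _wrap(x), _wrap(w)
    nd = x.data.ndim - 1
    stride = (stride,) * nd if np.isscalar(stride) else tuple(stride)
    pad = (pad,) * nd if np.isscalar(pad) else tuple(pad)
    cols = _im2col(x.data, w.data.shape[2:], stride, pad) if _tracked(x, w) else None
    y = _conv_fwd(x.data, w.data, stride, pad, cols=cols)

    def backward():
        if x.requires_grad or x._parents:
            x._accumulate(_conv_bwd_x(out.grad, w.data, stride, pad, x.data.shape))
        if w.requires_grad or w._parents:
            w._accumulate(_conv_bwd_w(x.data, out.grad, stride, pad,
                                      w.data.shape, cols=cols))

    out = _make(y, (x, w), backward)
    return out


def conv_transpose_nd(x: Tensor, w: Tensor, stride: int | Sequence[int] = 2,
                      pad: int | Sequence[int] = 1,
                      out_spatial: Sequence[int] | None = None) -> Tensor:
    """Transpose convolution: the adjoint of :func:`conv_nd`.

    ``w`` is shaped ``(Ci, Co, *k)``; the forward map sends ``(Ci, *S)`` to
    ``(Co, *T)`` where ``T`` defaults to ``stride * S`` (exact upsampling for
    kernel 3, stride 2, padding 1).
    """
    x, w = _wrap(x), _wrap(w)
    nd = x.data.ndim - 1
    stride = (stride,) * nd if np.isscalar(stride) else tuple(stride)
    pad = (pad,) * nd if np.isscalar(pad) else tuple(pad)
    if out_spatial is None:
        out_spatial = tuple(stride[i] * x.data.shape[i + 1] for i in range(nd))
    yshape = (w.data.shape[1],) + tuple(out_spatial)
    y = _conv_bwd_x(x.data, w.data, stride, pad, yshape)

    def backward():
        if x.requires_grad or x._parents:
            x._accumulate(_conv_fwd(out.grad, w.data, stride, pad))
        if w.requires_grad or w._parents:
            w._accumulate(_conv_bwd_w(out.grad, x.data, stride, pad, w.data.shape))

    out = _make(y, (x, w), backward)
    return out


# -- parameters and optimiser -------------------------------------------------


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def he_normal(shape: Sequence[int], fan_in: int, rng: np.random.Generator) -> Tensor:
    """He initialisation: N(0, 2 / fan_in)."""
    return parameter(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape))


class Adam:
    """Adam with the GAN-conventional beta_1 = 0.5 default."""

    def __init__(self, params: Iterable[Tensor], lr: float,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
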