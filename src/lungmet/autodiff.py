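"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides the :class:`Tensor` type plus the small set of
differentiable operations needed by the segmentation network and its
composite loss: elementwise arithmetic, matmul, ReLU, log/exp, reductions,
concatenation, stride-1 2D convolution (dense, depthwise and 1x1), an exact
2x2/stride-2 transposed convolution, max pooling, bilinear resizing, batch
normalisation, softmax, and two gather primitives used by the losses.

Gradients are accumulated by a topological backward sweep from a scalar
output. Only stride-1 convolutions are implemented; all spatial resolution
changes in the network go through pooling, bilinear resizing or the 2x2
transposed convolution, which keeps every backward pass expressible as
another stride-1 correlation.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "conv2d",
    "depthwise_conv2d",
    "conv_transpose2x2",
    "maxpool2d",
    "resize_bilinear",
    "batchnorm2d",
    "softmax_channel",
    "gather_class",
    "take_flat",
    "clipped_log",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- conveniences ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        o = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if o.requires_grad:
                o._accum(g)

        return Tensor._make(self.data + o.data, (self, o), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * o.data)
            if o.requires_grad:
                o._accum(g * self.data)

        return Tensor._make(self.data * o.data, (self, o), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g / o.data)
            if o.requires_grad:
                o._accum(-g * self.data / (o.data * o.data))

        return Tensor._make(self.data / o.data, (self, o), bwd)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bwd(g):
            self._accum(g * e * np.power(self.data, e - 1.0))

        return Tensor._make(np.power(self.data, e), (self,), bwd)

    def __matmul__(self, other):
        o = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ o.data.T)
            if o.requires_grad:
                o._accum(self.data.T @ g)

        return Tensor._make(self.data @ o.data, (self, o), bwd)

    # -- nonlinearities and reductions ------------------------------------

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.data.shape

        def bwd(g):
            self._accum(np.asarray(g).reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)


# ---------------------------------------------------------------------------
# Structural ops


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


def take_flat(x: Tensor, indices: np.ndarray) -> Tensor:
    """Gather from the flattened tensor; backward scatter-adds."""
    idx = np.asarray(indices)

    def bwd(g):
        dx = np.zeros(x.data.size, dtype=x.data.dtype)
        np.add.at(dx, idx.ravel(), np.asarray(g).ravel())
        x._accum(dx.reshape(x.data.shape))

    return Tensor._make(x.data.reshape(-1)[idx], (x,), bwd)


def gather_class(probs: Tensor, target: np.ndarray) -> Tensor:
    """Pick ``probs[n, target[n,h,w], h, w]`` -> (N, H, W).

    Each output location reads exactly one channel, so the backward pass is a
    collision-free scatter.
    """
    t = np.asarray(target)[:, None, :, :]
    out = np.take_along_axis(probs.data, t, axis=1)[:, 0]

    def bwd(g):
        dp = np.zeros_like(probs.data)
        np.put_along_axis(dp, t, np.asarray(g)[:, None], axis=1)
        probs._accum(dp)

    return Tensor._make(out, (probs,), bwd)


def clipped_log(p: Tensor, eps: float = 1e-7) -> Tensor:
    """log(clip(p, eps, 1)); gradient is zero where the clip is active."""
    clipped = np.clip(p.data, eps, 1.0)
    inside = (p.data >= eps) & (p.data <= 1.0)

    def bwd(g):
        p._accum(np.asarray(g) * inside / clipped)

    return Tensor._make(np.log(clipped), (p,), bwd)


# ---------------------------------------------------------------------------
# Convolutions (stride 1 only) and friends


def _corr2d(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Plain NumPy cross-correlation: x (N,C,H,W), w (Cout,C,kh,kw)."""
    kh, kw = w.shape[2], w.shape[3]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
    return np.einsum("nchwij,ocij->nohw", cols, w, optimize=True)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 0) -> Tensor:
    """Dense stride-1 convolution; x (N,C,H,W), w (Cout,C,kh,kw), b (Cout,)."""
    out_data = _corr2d(x.data, w.data, pad)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    kh = w.data.shape[2]
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        g = np.asarray(g)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            cols = sliding_window_view(xp, (kh, kh), axis=(2, 3))
            w._accum(np.einsum("nchwij,nohw->ocij", cols, g, optimize=True))
        if x.requires_grad:
            w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            x._accum(_corr2d(g, w_flip, kh - 1 - pad))

    return Tensor._make(out_data, parents, bwd)


def depthwise_conv2d(x: Tensor, w: Tensor, pad: int = 1) -> Tensor:
    """Per-channel stride-1 convolution; x (N,C,H,W), w (C,kh,kw)."""
    kh, kw = w.data.shape[1], w.data.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out_data = np.einsum("nchwij,cij->nchw", cols, w.data, optimize=True)

    def bwd(g):
        g = np.asarray(g)
        if w.requires_grad:
            w._accum(np.einsum("nchwij,nchw->cij", cols, g, optimize=True))
        if x.requires_grad:
            w_flip = w.data[:, ::-1, ::-1]
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1 - pad,) * 2, (kw - 1 - pad,) * 2))
            gcols = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            x._accum(np.einsum("nchwij,cij->nchw", gcols, w_flip, optimize=True))

    return Tensor._make(out_data, (x, w), bwd)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Exact 2x upsampling transposed convolution (kernel 2, stride 2).

    x (N,C,H,W), w (C,Cout,2,2) -> (N,Cout,2H,2W). Output pixels tile without
    overlap, so both directions are single einsums.
    """
    N, C, H, W = x.data.shape
    Cout = w.data.shape[1]
    out6 = np.einsum("nchw,cdij->ndhiwj", x.data, w.data, optimize=True)
    out_data = out6.reshape(N, Cout, 2 * H, 2 * W)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        g6 = np.asarray(g).reshape(N, Cout, H, 2, W, 2)
        if b is not None and b.requires_grad:
            b._accum(np.asarray(g).sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum(np.einsum("nchw,ndhiwj->cdij", x.data, g6, optimize=True))
        if x.requires_grad:
            x._accum(np.einsum("ndhiwj,cdij->nchw", g6, w.data, optimize=True))

    return Tensor._make(out_data, parents, bwd)


def maxpool2d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping max pooling by an integer factor dividing H and W."""
    N, C, H, W = x.data.shape
    f = int(factor)
    Ho, Wo = H // f, W // f
    xr = (
        x.data.reshape(N, C, Ho, f, Wo, f)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, Ho, Wo, f * f)
    )
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], np.asarray(g)[..., None], axis=-1)
        dx = (
            dxr.reshape(N, C, Ho, Wo, f, f)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )
        x._accum(dx)

    return Tensor._make(out_data, (x,), bwd)


_RESIZE_CACHE: dict = {}


def _bilinear_matrix(n_in: int, factor: int, dtype) -> np.ndarray:
    """1D bilinear interpolation matrix (factor*n_in, n_in), half-pixel centers."""
    key = (n_in, factor, np.dtype(dtype).str)
    if key not in _RESIZE_CACHE:
        n_out = n_in * factor
        A = np.zeros((n_out, n_in))
        src = (np.arange(n_out) + 0.5) / factor - 0.5
        i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
        i1 = np.clip(i0 + 1, 0, n_in - 1)
        t = np.clip(src - np.floor(src), 0.0, 1.0)
        t[src < 0] = 0.0
        np.add.at(A, (np.arange(n_out), i0), 1.0 - t)
        np.add.at(A, (np.arange(n_out), i1), t)
        _RESIZE_CACHE[key] = A.astype(dtype)
    return _RESIZE_CACHE[key]


def resize_bilinear(x: Tensor, factor: int) -> Tensor:
    """Upscale H and W by an integer factor with bilinear interpolation."""
    N, C, H, W = x.data.shape
    Ay = _bilinear_matrix(H, factor, x.data.dtype)
    Ax = _bilinear_matrix(W, factor, x.data.dtype)
    out_data = np.einsum("ij,ncjk,lk->ncil", Ay, x.data, Ax, optimize=True)

    def bwd(g):
        x._accum(np.einsum("ij,ncil,lk->ncjk", Ay, np.asarray(g), Ax, optimize=True))

    return Tensor._make(out_data, (x,), bwd)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Channelwise batch normalisation over (N, H, W).

    In training mode batch statistics are used and the running buffers are
    updated in place; in inference mode the running buffers are used.
    """
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(g):
        g = np.asarray(g)
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = g * gamma.data[None, :, None, None]
            if training:
                m1 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
                m2 = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = (dxhat - m1 - xhat * m2) * inv_std[None, :, None, None]
            else:
                dx = dxhat * inv_std[None, :, None, None]
            x._accum(dx)

    return Tensor._make(out_data, (x, gamma, beta), bwd)


def softmax_channel(x: Tensor) -> Tensor:
    """Softmax over axis 1 of an (N, C, H, W) tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)

    def bwd(g):
        g = np.asarray(g)
        x._accum(s * (g - (g * s).sum(axis=1, keepdims=True)))

    return Tensor._make(s, (x,), bwd)
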