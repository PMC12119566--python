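"""Differentiable operations for the tiny autodiff engine.

Convolution uses im2col (``numpy.lib.stride_tricks.sliding_window_view``)
with cached scatter indices for the input gradient.  Downsampling and
upsampling convolutions use non-overlapping 2x2x2 kernels (kernel = stride),
which reduce to reshapes plus an einsum and are therefore cheap on CPU.
"""

from __future__ import annotations

import functools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, astensor

__all__ = [
    "add", "mul", "mulc", "addc", "powc", "exp", "log", "sigmoid", "relu", "sum", "mean",
    "amax", "reshape", "transpose", "concat", "getitem", "logsoftmax", "softmax",
    "conv3d", "downconv2", "upconv2", "upsample_trilinear",
    "global_avg_pool", "global_max_pool",
]


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _needs_grad(*tensors):
    return any(t.requires_grad or t._backward is not None for t in tensors)


def _make(data, parents, backward):
    if _needs_grad(*parents):
        return Tensor._from_op(data, tuple(parents), backward)
    return Tensor._from_op(data, (), None)


# ----------------------------------------------------------------------
# elementwise
# ----------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def mulc(a: Tensor, c: float) -> Tensor:
    """Multiply by a Python scalar (keeps the tensor's dtype and, on the
    float64 path, the scalar's full double precision)."""
    a = astensor(a)
    c = float(c)
    out_data = a.data * c

    def backward(g):
        a._accumulate(g * c)

    return _make(out_data, (a,), backward)


def addc(a: Tensor, c: float) -> Tensor:
    """Add a Python scalar."""
    a = astensor(a)
    out_data = a.data + float(c)

    def backward(g):
        a._accumulate(g)

    return _make(out_data, (a,), backward)


def powc(a: Tensor, exponent: float) -> Tensor:
    a = astensor(a)
    out_data = a.data ** exponent

    def backward(g):
        a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    a = astensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = astensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def backward(g):
        a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


# ----------------------------------------------------------------------
# reductions / shape
# ----------------------------------------------------------------------

def sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            g = np.expand_dims(g, tuple(sorted(axes)))
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return _make(out_data, (a,), backward)


def mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mulc(sum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def amax(a: Tensor, axis, keepdims=False) -> Tensor:
    """Max-reduce along ``axis``; gradient flows to the (first) argmax."""
    a = astensor(a)
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out_data).astype(a.data.dtype)
    # split ties evenly so the gradient check stays sane
    mask = mask / mask.sum(axis=axis, keepdims=True)
    result = out_data if keepdims else np.squeeze(out_data, axis=axis)

    def backward(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(g * mask)

    return _make(result, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(np.asarray(g).reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    a = astensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(np.asarray(g).transpose(inv))

    return _make(out_data, (a,), backward)


def concat(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(np.asarray(g), splits, axis=axis)):
            t._accumulate(piece)

    return _make(out_data, tuple(tensors), backward)


def getitem(a: Tensor, idx) -> Tensor:
    """Basic (non-fancy) indexing with gradient scatter."""
    a = astensor(a)
    out_data = a.data[idx]

    def backward(g):
        gx = np.zeros_like(a.data)
        gx[idx] += g
        a._accumulate(gx)

    return _make(out_data, (a,), backward)


def logsoftmax(a: Tensor, axis=1) -> Tensor:
    a = astensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse

    def backward(g):
        g = np.asarray(g)
        soft = np.exp(out_data)
        a._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), backward)


def softmax(a: Tensor, axis=1) -> Tensor:
    return exp(logsoftmax(a, axis=axis))


# ----------------------------------------------------------------------
# convolution
# ----------------------------------------------------------------------

@functools.lru_cache(maxsize=64)
def _col2im_indices(padded_shape, kernel, out_spatial):
    """Flat indices into a padded (C, D, H, W) volume for each im2col column."""
    C, D, H, W = padded_shape
    kd, kh, kw = kernel
    od, oh, ow = out_spatial
    c, dz, dy, dx = np.meshgrid(
        np.arange(C), np.arange(kd), np.arange(kh), np.arange(kw), indexing="ij"
    )
    base = (c * D + dz) * H * W + dy * W + dx  # (C, kd, kh, kw)
    oz, oy, ox = np.meshgrid(np.arange(od), np.arange(oh), np.arange(ow), indexing="ij")
    offset = (oz * H + oy) * W + ox  # (od, oh, ow)
    idx = base.reshape(-1, 1) + offset.reshape(1, -1)
    return idx.ravel()


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 1) -> Tensor:
    """3D cross-correlation, stride 1, symmetric zero padding.

    ``x``: (N, Cin, D, H, W); ``w``: (Cout, Cin, kd, kh, kw); ``b``: (Cout,).
    """
    x, w = astensor(x), astensor(w)
    N, Cin, D, H, W = x.data.shape
    Cout, _, kd, kh, kw = w.data.shape
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    od, oh, ow = D + 2 * p - kd + 1, H + 2 * p - kh + 1, W + 2 * p - kw + 1
    # (N, Cin, od, oh, ow, kd, kh, kw) view, no copy
    win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    cols = win.transpose(0, 1, 5, 6, 7, 2, 3, 4).reshape(N, Cin * kd * kh * kw, -1)
    wmat = w.data.reshape(Cout, -1)
    out = np.einsum("ok,nkl->nol", wmat, cols, optimize=True)
    out_data = out.reshape(N, Cout, od, oh, ow)
    if b is not None:
        b = astensor(b)
        out_data = out_data + b.data.reshape(1, Cout, 1, 1, 1)

    cols_saved = cols  # needed for grad_w

    def backward(g):
        g = np.asarray(g).reshape(N, Cout, -1)
        gw = np.einsum("nol,nkl->ok", g, cols_saved, optimize=True)
        w._accumulate(gw.reshape(w.data.shape))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2)))
        gcols = np.einsum("ok,nol->nkl", wmat, g, optimize=True)
        idx = _col2im_indices((Cin,) + xp.shape[2:], (kd, kh, kw), (od, oh, ow))
        gx = np.zeros((N, xp[0].size), dtype=x.data.dtype)
        for n in range(N):
            np.add.at(gx[n], idx, gcols[n].ravel())
        gx = gx.reshape(N, Cin, *xp.shape[2:])
        if p:
            gx = gx[:, :, p:-p, p:-p, p:-p]
        x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def downconv2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Strided 2x2x2 convolution (kernel = stride: non-overlapping blocks).

    Halves each spatial dimension.  ``w``: (Cout, Cin, 2, 2, 2).
    """
    x, w = astensor(x), astensor(w)
    N, Cin, D, H, W = x.data.shape
    Cout = w.data.shape[0]
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"downconv2 needs even spatial dims, got {(D, H, W)}")
    blocks = x.data.reshape(N, Cin, D // 2, 2, H // 2, 2, W // 2, 2)
    out_data = np.einsum("ncdihjwk,ocijk->nodhw", blocks, w.data, optimize=True)
    if b is not None:
        b = astensor(b)
        out_data = out_data + b.data.reshape(1, Cout, 1, 1, 1)

    def backward(g):
        g = np.asarray(g)
        gw = np.einsum("nodhw,ncdihjwk->ocijk", g, blocks, optimize=True)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        gx = np.einsum("nodhw,ocijk->ncdihjwk", g, w.data, optimize=True)
        x._accumulate(gx.reshape(N, Cin, D, H, W))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def upconv2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed 2x2x2 convolution, stride 2 (exact inverse geometry of
    :func:`downconv2`).  ``w``: (Cin, Cout, 2, 2, 2).  Doubles spatial dims.
    """
    x, w = astensor(x), astensor(w)
    N, Cin, D, H, W = x.data.shape
    Cout = w.data.shape[1]
    out = np.einsum("ncdhw,coijk->nodihjwk", x.data, w.data, optimize=True)
    out_data = out.reshape(N, Cout, 2 * D, 2 * H, 2 * W)
    if b is not None:
        b = astensor(b)
        out_data = out_data + b.data.reshape(1, Cout, 1, 1, 1)

    def backward(g):
        g = np.asarray(g).reshape(N, Cout, D, 2, H, 2, W, 2)
        gw = np.einsum("ncdhw,nodihjwk->coijk", x.data, g, optimize=True)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3, 4, 5, 6, 7)))
        gx = np.einsum("nodihjwk,coijk->ncdhw", g, w.data, optimize=True)
        x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


# ----------------------------------------------------------------------
# interpolation / pooling
# ----------------------------------------------------------------------

@functools.lru_cache(maxsize=128)
def _linear_interp_weights(n_in: int, factor: int):
    """Source indices and weights for 1D linear upsampling (align_corners
    False, edge clamped), matching the usual half-pixel-center convention."""
    n_out = n_in * factor
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    lo = np.floor(src).astype(np.int64)
    frac = (src - lo).astype(np.float32)
    hi = np.clip(lo + 1, 0, n_in - 1)
    lo = np.clip(lo, 0, n_in - 1)
    return lo, hi, 1.0 - frac, frac


def _interp_axis(x: Tensor, factor: int, axis: int) -> Tensor:
    x = astensor(x)
    n_in = x.data.shape[axis]
    lo, hi, w_lo, w_hi = _linear_interp_weights(n_in, factor)
    shape = [1] * x.data.ndim
    shape[axis] = -1
    out_data = (
        np.take(x.data, lo, axis=axis) * w_lo.reshape(shape)
        + np.take(x.data, hi, axis=axis) * w_hi.reshape(shape)
    )

    def backward(g):
        g = np.asarray(g)
        gx = np.zeros_like(x.data)
        gm = np.moveaxis(gx, axis, 0)
        gg = np.moveaxis(g, axis, 0)
        np.add.at(gm, lo, gg * np.moveaxis(np.broadcast_to(w_lo.reshape(shape), g.shape), axis, 0))
        np.add.at(gm, hi, gg * np.moveaxis(np.broadcast_to(w_hi.reshape(shape), g.shape), axis, 0))
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def upsample_trilinear(x: Tensor, factor: int) -> Tensor:
    """Trilinear upsampling of (N, C, D, H, W) by an integer ``factor``."""
    if factor == 1:
        return astensor(x)
    out = x
    for axis in (2, 3, 4):
        out = _interp_axis(out, factor, axis)
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, D, H, W) -> (N, C, 1, 1, 1) mean over space."""
    return mean(x, axis=(2, 3, 4), keepdims=True)


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, D, H, W) -> (N, C, 1, 1, 1) max over space."""
    return amax(x, axis=(2, 3, 4), keepdims=True)
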