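"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations that
produced it; calling :meth:`Tensor.backward` on a scalar result accumulates
gradients into every upstream tensor created with ``requires_grad=True``.
Only the operations needed by the segmentation network and its losses are
provided — this is a deliberately small engine, not a general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor"]


class Tensor:
    """A NumPy array with a gradient tape.

    Parameters
    ----------
    data : array-like
        Values; converted to ``float32``.
    requires_grad : bool
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # keep ndarray.__mul__ etc. from consuming Tensors elementwise;
    # arithmetic with arrays must route through our operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        data = np.asarray(data)
        # float64 arrays keep their precision (loss-formula verification);
        # scalars and everything else become float32 so that mixing in
        # Python floats never upcasts the fast float32 network path
        if data.dtype != np.float64 or data.ndim == 0:
            data = data.astype(np.float32, copy=False)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    @classmethod
    def _from_op(cls, data, parents, backward):
        """Wrap an op result, preserving its floating dtype (including 0-d
        float64 reductions — only leaf scalars are forced to float32)."""
        t = cls.__new__(cls)
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float32)
        t.data = data
        t.grad = None
        t.requires_grad = backward is not None
        t._parents = parents
        t._backward = backward
        return t

    # ------------------------------------------------------------------
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

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self):
        """Backpropagate from a scalar tensor through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype).copy()
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------
    # Python/NumPy scalars route through dedicated constant ops so they
    # neither upcast the float32 path nor lose double precision on the
    # float64 path.
    def __add__(self, other):
        from . import functional as F

        if _is_scalar(other):
            return F.addc(self, other)
        return F.add(self, astensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        from . import functional as F

        if _is_scalar(other):
            return F.mulc(self, other)
        return F.mul(self, astensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        from . import functional as F

        return F.mulc(self, -1.0)

    def __sub__(self, other):
        from . import functional as F

        if _is_scalar(other):
            return F.addc(self, -float(other))
        return F.add(self, F.mulc(astensor(other), -1.0))

    def __rsub__(self, other):
        from . import functional as F

        if _is_scalar(other):
            return F.addc(F.mulc(self, -1.0), other)
        return F.add(astensor(other), F.mulc(self, -1.0))

    def __truediv__(self, other):
        from . import functional as F

        if _is_scalar(other):
            return F.mulc(self, 1.0 / float(other))
        return F.mul(self, F.powc(astensor(other), -1.0))

    def __rtruediv__(self, other):
        from . import functional as F

        if _is_scalar(other):
            return F.mulc(F.powc(self, -1.0), other)
        return F.mul(astensor(other), F.powc(self, -1.0))

    def __pow__(self, exponent):
        from . import functional as F

        return F.powc(self, float(exponent))

    def __getitem__(self, idx):
        from . import functional as F

        return F.getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        from . import functional as F

        return F.sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        from . import functional as F

        return F.mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        from . import functional as F

        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return F.reshape(self, shape)


def _is_scalar(x) -> bool:
    if isinstance(x, Tensor):
        return False
    return np.isscalar(x) or (isinstance(x, np.ndarray) and x.ndim == 0)


def astensor(x) -> Tensor:
    """Wrap ``x`` in a constant :class:`Tensor` unless it already is one."""
    if isinstance(x, Tensor):
        return x
    return Tensor(x)
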