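"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The network code in this package needs gradients of a handful of array
operations (dense products, elementwise nonlinearities, reductions,
reshapes, concatenation and fancy indexing).  This module provides a small
tape-based :class:`Tensor` supporting exactly those operations, with
broadcasting handled by summing gradients back to the operand shape.
Convolution primitives with bespoke backward rules live in
:mod:`protoerp.nn.layers`.

All operations are validated against central finite differences in the test
suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "no_grad", "concat"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _sum_to(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` (a broadcast result) back to ``shape``."""
    if grad.shape == tuple(shape):
        return grad
    # sum over leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size 1 in the operand
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad = None
        self._parents: tuple = ()
        self._backward = None
        self._grad_borrowed = False

    # -- graph construction ------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        # The first gradient is kept by reference (most nodes have a single
        # consumer); a second contribution forces an owned copy before the
        # in-place accumulation, so shared upstream arrays stay untouched.
        if self.grad is None:
            self.grad = g
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + g
            self._grad_borrowed = False
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (must be scalar if grad is None)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free graph references as we go
                node._backward = None
                node._parents = ()

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_sum_to(g, a.shape))
            if b.requires_grad:
                b._accum(_sum_to(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_sum_to(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_sum_to(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_sum_to(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_sum_to(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        return Tensor._make(a.data ** e, (a,), bwd)

    def matmul(self, other):
        other = Tensor._coerce(other)
        a, b = self, other
        out = a.data @ b.data

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_sum_to(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_sum_to(gb, b.shape))

        return Tensor._make(out, (a, b), bwd)

    __matmul__ = matmul

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(np.where(mask, a.data, 0.0), (a,), bwd)

    def elu(self, alpha: float = 1.0):
        a = self
        neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
        pos_mask = a.data > 0
        out_data = np.where(pos_mask, a.data, neg)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * np.where(pos_mask, 1.0, neg + alpha))

        return Tensor._make(out_data, (a,), bwd)

    def clip(self, lo, hi):
        """Clamp values; gradient is zero outside the active range."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), bwd)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            if a.requires_grad:
                a._accum(g.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            if a.requires_grad:
                full = np.zeros_like(a.data, dtype=g.dtype)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(a.data[idx], (a,), bwd)

    # -- composite helpers -------------------------------------------------

    def softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        m = np.max(self.data, axis=axis, keepdims=True)
        s = (self - m).exp().sum(axis=axis, keepdims=True).log() + m
        if not keepdims:
            s = s.reshape(tuple(np.delete(s.shape, axis)))
        return s

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )
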