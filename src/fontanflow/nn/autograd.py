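"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains two small neural networks (a space-time encoder/decoder
segmentation network and a temporal autoencoder); this module provides the
tensor type and differentiable operations they are built from.  The design
follows the usual define-by-run pattern: every operation records its parents
and a closure that propagates the upstream gradient, and ``Tensor.backward``
runs the closures in reverse topological order.

Only what the networks need is implemented: broadcasting arithmetic, matmul,
pointwise nonlinearities, reductions, shape ops, softmax and convolutions
(see :mod:`fontanflow.nn.functional` for the convolution/pooling kernels).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _make(self, data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=[p for p in parents if p.requires_grad],
                      backward=backward if req else None)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = self._lift(other)
        out_data = self.data + o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.shape))

        return self._make(out_data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        o = self._lift(other)
        out_data = self.data * o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.shape))

        return self._make(out_data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._lift(other)
        out_data = self.data / o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data ** 2), o.shape))

        return self._make(out_data, (self, o), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), bw)

    def __matmul__(self, other):
        o = self._lift(other)
        out_data = self.data @ o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(o.data, -1, -2), self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, o.shape))

        return self._make(out_data, (self, o), bw)

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g):
            self._accum(g * mask)

        return self._make(out_data, (self,), bw)

    def clip_min(self, lo: float):
        mask = self.data > lo
        out_data = np.maximum(self.data, lo)

        def bw(g):
            self._accum(g * mask)

        return self._make(out_data, (self,), bw)

    # -- reductions and shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return self._make(out_data, (self,), bw)

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), bw)

    def dropout(self, p: float, rng: np.random.Generator, training: bool = True):
        if not training or p <= 0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)
        mask = mask.astype(self.data.dtype)

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)


def concat(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  parents=[t for t in tensors if t.requires_grad],
                  backward=bw if req else None)


def stack(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  parents=[t for t in tensors if t.requires_grad],
                  backward=bw if req else None)
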