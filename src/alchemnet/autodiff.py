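"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the message-passing network needs: dense
affine maps, elementwise arithmetic, SiLU, row gather / segment scatter-add
(the message-passing primitives), concatenation and reductions. Gradients are
accumulated in float64 regardless of the forward dtype of the data.

The engine is deliberately small; it is validated against central finite
differences in the test suite rather than aiming for generality.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "parameter", "matmul", "add", "sub", "mul",
    "silu", "concat", "gather_rows", "segment_sum", "sum_all", "mean_all",
    "square", "scale", "affine",
]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad = self.grad + g


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    out._backward = bwd
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, parents=(a, b))

    def bwd(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(-_unbroadcast(g, b.shape))

    out._backward = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    out._backward = bwd
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * c, parents=(a,))
    out._backward = lambda g: a._accum(g * c)
    return out


def square(a: Tensor) -> Tensor:
    out = Tensor(a.data ** 2, parents=(a,))
    out._backward = lambda g: a._accum(2.0 * g * a.data)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bwd(g):
        a._accum(g @ b.data.T)
        b._accum(a.data.T @ g)

    out._backward = bwd
    return out


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def silu(a: Tensor) -> Tensor:
    sig = _sigmoid(a.data)
    out = Tensor(a.data * sig, parents=(a,))
    # d/dx x*sig(x) = sig(x) * (1 + x*(1-sig(x)))
    out._backward = lambda g: a._accum(g * sig * (1.0 + a.data * (1.0 - sig)))
    return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bwd
    return out


def gather_rows(a: Tensor, idx) -> Tensor:
    """Select rows ``a[idx]``; gradient is a scatter-add back into ``a``."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(a.data[idx], parents=(a,))

    def bwd(g):
        acc = np.zeros_like(a.data)
        np.add.at(acc, idx, g)
        a._accum(acc)

    out._backward = bwd
    return out


def segment_sum(a: Tensor, seg_ids, n_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``n_segments`` buckets; gradient is a gather."""
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    acc = np.zeros((n_segments,) + a.data.shape[1:])
    np.add.at(acc, seg_ids, a.data)
    out = Tensor(acc, parents=(a,))
    out._backward = lambda g: a._accum(g[seg_ids])
    return out


def sum_all(a: Tensor) -> Tensor:
    out = Tensor(a.data.sum(), parents=(a,))
    out._backward = lambda g: a._accum(np.full(a.shape, float(g)))
    return out


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size
    out = Tensor(a.data.mean(), parents=(a,))
    out._backward = lambda g: a._accum(np.full(a.shape, float(g) / n))
    return out


def affine(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x @ w + b (bias broadcast over rows)."""
    return add(matmul(x, w), b)
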