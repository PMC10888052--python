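"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: dense float32 tensors, a dynamic tape built by
the operations below, and a topological-sort backward pass.  It exists so the
segmentation network can be trained and differentiated with only numpy/scipy
as runtime dependencies.  Only the operations the network and its losses need
are implemented; each op defines its own vector-Jacobian product.
"""

from __future__ import annotations

import contextlib
from typing import Iterable

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / metric evaluation)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """A numpy array plus an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp = None  # callable grad_out -> tuple of parent grads

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
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _make(data, parents: Iterable["Tensor"], vjp) -> "Tensor":
        parents = tuple(parents)
        track = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = parents
            out._vjp = vjp
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep at 3D-network scale
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not (p.requires_grad or p._vjp is not None):
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def vjp(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), vjp)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data
        a, b = self, other

        def vjp(g):
            return (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            )

        return Tensor._make(out_data, (a, b), vjp)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other._reciprocal()
        return self * (1.0 / float(other))

    def _reciprocal(self):
        inv = 1.0 / self.data

        def vjp(g):
            return (-g * inv * inv,)

        return Tensor._make(inv, (self,), vjp)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = self.data @ other.data
        a, b = self, other

        def vjp(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._make(out, (a, b), vjp)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).astype(np.float32),)

        return Tensor._make(out, (self,), vjp)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out = self.data.max(axis=axis, keepdims=keepdims)
        arg = np.expand_dims(self.data.argmax(axis=axis), axis)
        shape = self.shape

        def vjp(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros(shape, dtype=np.float32)
            np.put_along_axis(full, arg, g, axis=axis)
            return (full,)

        return Tensor._make(out, (self,), vjp)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        def vjp(g):
            return (g / self.data,)

        return Tensor._make(np.log(self.data), (self,), vjp)

    def sigmoid(self):
        x = self.data
        out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(np.float32)
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def elu(self, alpha: float = 1.0):
        neg = self.data < 0
        expm = np.where(neg, np.exp(np.minimum(self.data, 0.0)), 1.0)
        out = np.where(neg, alpha * (expm - 1.0), self.data).astype(np.float32)

        def vjp(g):
            return ((g * np.where(neg, alpha * expm, 1.0)).astype(np.float32),)

        return Tensor._make(out, (self,), vjp)

    def relu(self):
        mask = self.data > 0

        def vjp(g):
            return (g * mask,)

        return Tensor._make(self.data * mask, (self,), vjp)

    def clip(self, lo: float, hi: float):
        """Clamp; gradient is zero outside [lo, hi] (hard clip, not straight-through)."""
        inside = (self.data >= lo) & (self.data <= hi)

        def vjp(g):
            return (g * inside,)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), vjp)

    # ----------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def vjp(g):
            return (g.reshape(old),)

        return Tensor._make(self.data.reshape(shape), (self,), vjp)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def vjp(g):
            return (g.transpose(inv),)

        return Tensor._make(self.data.transpose(axes), (self,), vjp)

    def __getitem__(self, idx):
        shape = self.shape

        def vjp(g):
            full = np.zeros(shape, dtype=np.float32)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), vjp)


def concatenate(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tensors, vjp)


def stack_mean(tensors: list[Tensor]) -> Tensor:
    """Mean of same-shaped scalars/tensors (used for batch loss averaging)."""
    acc = tensors[0]
    for t in tensors[1:]:
        acc = acc + t
    return acc * (1.0 / len(tensors))
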