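"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training stack in this package needs gradients for a handful of dense
operations (matmul, elementwise nonlinearities, reductions, gather,
concatenation).  Rather than depend on a deep-learning framework, this module
implements a small tape-based autodiff engine: each :class:`Tensor` wraps a
float64 ndarray and records a closure that accumulates gradients into its
parents.  ``backward`` runs a topological sort and applies the closures in
reverse order.

All arrays are float64.  Broadcasting follows numpy semantics; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "logsumexp",
    "softmax",
    "stack",
]

_GELU_C = math.sqrt(2.0 / math.pi)
_GELU_A = 0.044715


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from 1
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = _parents

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable parent."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS (graphs can exceed the recursion limit)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents
                         if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                stack.pop()
                topo.append(node)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        # grads are never mutated in place, so storing a view is safe
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            shape = out.data.shape

            def _backward(g):
                if self.requires_grad:
                    self._accumulate(g if self.shape == shape
                                     else _unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(g if other.shape == shape
                                      else _unbroadcast(g, other.shape))
            out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def _backward(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))
        if out.requires_grad:
            def _backward(g):
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))
            out._backward = _backward
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        return self.pow(exponent)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        if self.ndim < 2 or other.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2")
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def _backward(g):
                if self.requires_grad:
                    ga = g @ other.data.swapaxes(-1, -2)
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = self.data.swapaxes(-1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.shape))
            out._backward = _backward
        return out

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1.0 - out.data ** 2))
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (self.data > 0.0))
        return out

    def gelu(self) -> "Tensor":
        # tanh approximation; exact enough for training, cheap single node
        x = self.data
        u = _GELU_C * (x + _GELU_A * x ** 3)
        t = np.tanh(u)
        out = Tensor(0.5 * x * (1.0 + t), self.requires_grad, (self,))
        if out.requires_grad:
            def _backward(g):
                du = _GELU_C * (1.0 + 3.0 * _GELU_A * x ** 2)
                self._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * du))
            out._backward = _backward
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        if out.requires_grad:
            def _backward(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.shape))
                    return
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, axes)
                self._accumulate(np.broadcast_to(g, self.shape))
            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inverse = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.transpose(inverse))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(tuple(axes))

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if out.requires_grad:
            def _backward(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = _backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def zero_pad(x: Tensor, pad_width: Sequence[tuple[int, int]]) -> Tensor:
    """Zero-pad along each axis; backward slices the padding back off."""
    out = Tensor(np.pad(x.data, pad_width), x.requires_grad, (x,))
    if out.requires_grad:
        sl = tuple(slice(lo, lo + n) for (lo, _), n in zip(pad_width, x.shape))
        out._backward = lambda g: x._accumulate(g[sl])
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def _backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])
        out._backward = _backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = as_tensor(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(tuple(shape)))
    return concat(expanded, axis=axis)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp; the max shift is treated as constant."""
    m = np.max(x.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    shifted = x - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        out = out.reshape(tuple(s for i, s in enumerate(out.shape)
                                if i != (axis % x.ndim)))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return (x - logsumexp(x, axis=axis, keepdims=True)).exp()
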