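"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operator set needed by the embedding networks and the
training objectives: broadcasting arithmetic, matrix product, ReLU, exp/log,
power with a constant exponent, axis reductions and 2-D transpose.  Gradients
are accumulated by topological-order backpropagation from a scalar root.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "log_softmax", "l2_normalize_rows", "pairwise_sq_dists"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar root")
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))
        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only constant exponents are supported")
        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))
        return Tensor._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def relu(self):
        mask = self.data > 0
        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)
        return Tensor._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)
        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)
        return Tensor._make(np.log(self.data), (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    @property
    def T(self) -> "Tensor":
        if self.data.ndim != 2:
            raise ValueError("T is defined for 2-D tensors only")
        def backward(g):
            if self.requires_grad:
                self._accum(g.T)
        return Tensor._make(self.data.T, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def log_softmax(z: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable log-softmax along `axis` (max shift is a constant)."""
    z = as_tensor(z)
    shift = z - np.max(z.data, axis=axis, keepdims=True)
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def l2_normalize_rows(x: Tensor, eps: float = 0.0) -> Tensor:
    """Scale every row of a 2-D tensor to unit Euclidean norm."""
    x = as_tensor(x)
    sq = (x * x).sum(axis=1, keepdims=True)
    if np.any(sq.data <= 0) and eps == 0.0:
        raise ValueError("cannot L2-normalize a zero row")
    return x / ((sq + eps) ** 0.5)


def pairwise_sq_dists(a: Tensor, b: Tensor) -> Tensor:
    """All squared Euclidean distances between rows of `a` and rows of `b`."""
    a, b = as_tensor(a), as_tensor(b)
    aa = (a * a).sum(axis=1, keepdims=True)
    bb = (b * b).sum(axis=1, keepdims=True)
    d = aa + bb.T - 2.0 * (a @ b.T)
    # clamp tiny negatives from cancellation without breaking the tape
    return d.relu()
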