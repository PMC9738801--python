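"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the package's models need: broadcasting
arithmetic, 2-D matrix products, elementwise nonlinearities, axis
reductions and reshapes. Everything is float64; gradients accumulate into
``Tensor.grad`` when :meth:`Tensor.backward` is called on a scalar node.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "logsumexp", "softmax", "l2_normalize"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ---------------------------------------------------------------- helpers
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def backward(g):
            return _unbroadcast(g * b, self.shape), _unbroadcast(g * a, other.shape)

        return self._make(a * b, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self.data

        def backward(g):
            return (g * p * a ** (p - 1.0),)

        return self._make(a ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        if self.ndim != 2 or other.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        a, b = self.data, other.data

        def backward(g):
            return g @ b.T, a.T @ g

        return self._make(a @ b, (self, other), backward)

    # ----------------------------------------------------------- elementwise
    def tanh(self):
        t = np.tanh(self.data)
        return self._make(t, (self,), lambda g: (g * (1.0 - t * t),))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        e = np.exp(self.data)
        return self._make(e, (self,), lambda g: (g * e,))

    def log(self):
        a = self.data
        return self._make(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        return self ** 0.5

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        a_shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a_shape).copy(),)
            g_ = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_, a_shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a_shape = self.shape

        def backward(g):
            return (g.reshape(a_shape),)

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self):
        if self.ndim != 2:
            raise ValueError("transpose supports 2-D tensors only")
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    @property
    def T(self):
        return self.transpose()

    # --------------------------------------------------------------- autodiff
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


# --------------------------------------------------------------- composites

def logsumexp(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along ``axis`` (max treated as constant)."""
    m = np.max(x.data, axis=axis, keepdims=True)
    out = (x - Tensor(m)).exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    return out if keepdims else out.reshape(tuple(n for i, n in enumerate(x.shape) if i != axis % x.ndim))


def softmax(x: Tensor, axis: int) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    e = (x - Tensor(m)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def l2_normalize(x: Tensor, axis: int = 1, eps: float = 0.0) -> Tensor:
    """Rows scaled to unit Euclidean norm. Raises on a zero-norm row."""
    sq = (x * x).sum(axis=axis, keepdims=True)
    if np.any(sq.data <= eps):
        raise ValueError("cannot normalize a zero-norm vector")
    return x / sq.sqrt()
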