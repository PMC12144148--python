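"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the 1-D sequence generators/discriminators in
this package are provided: broadcasting arithmetic, 2-D matrix products,
pointwise nonlinearities, reductions, reshaping and basic slicing.  Gradients
are dense float64 arrays; graphs are built eagerly and freed after
``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "log", "exp", "tanh", "sigmoid", "sqrt", "relu",
           "leaky_relu", "clip"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
                if g is None or not parent.requires_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g
            node._backward = None
            node._parents = ()

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._node(out_data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        a, b = self, other

        def bwd(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))

        return Tensor._node(out_data, (a, b), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out_data = a.data / b.data

        def bwd(g):
            return (_unbroadcast(g / b.data, a.data.shape),
                    _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._node(out_data, (a, b), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self
        out_data = a.data ** p

        def bwd(g):
            return (g * p * a.data ** (p - 1),)

        return Tensor._node(out_data, (a,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        a, b = self, other
        out_data = a.data @ b.data

        def bwd(g):
            return (g @ b.data.T, a.data.T @ g)

        return Tensor._node(out_data, (a, b), bwd)

    # -- reductions / shaping -----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.data.shape).copy(),)

        return Tensor._node(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[i] for i in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out_data = a.data.reshape(shape)

        def bwd(g):
            return (g.reshape(a.data.shape),)

        return Tensor._node(out_data, (a,), bwd)

    def transpose(self, *axes):
        a = self
        axes = axes or None
        out_data = a.data.transpose(axes)
        inv = np.argsort(axes) if axes else None

        def bwd(g):
            return (g.transpose(inv) if inv is not None else g.transpose(),)

        return Tensor._node(out_data, (a,), bwd)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._node(out_data, (a,), bwd)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- pointwise functions ------------------------------------------------------

def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.log(x.data)

    def bwd(g):
        return (g / x.data,)

    return Tensor._node(out_data, (x,), bwd)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.exp(x.data)

    def bwd(g):
        return (g * out_data,)

    return Tensor._node(out_data, (x,), bwd)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.tanh(x.data)

    def bwd(g):
        return (g * (1.0 - out_data ** 2),)

    return Tensor._node(out_data, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        return (g * out_data * (1.0 - out_data),)

    return Tensor._node(out_data, (x,), bwd)


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.sqrt(x.data)

    def bwd(g):
        return (g * 0.5 / out_data,)

    return Tensor._node(out_data, (x,), bwd)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def bwd(g):
        return (g * mask,)

    return Tensor._node(out_data, (x,), bwd)


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, alpha * x.data)

    def bwd(g):
        return (g * np.where(mask, 1.0, alpha),)

    return Tensor._node(out_data, (x,), bwd)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values to [lo, hi]; gradient is passed through the interior only."""
    x = as_tensor(x)
    out_data = np.clip(x.data, lo, hi)
    mask = (x.data > lo) & (x.data < hi)

    def bwd(g):
        return (g * mask,)

    return Tensor._node(out_data, (x,), bwd)
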