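"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine providing exactly the operations the ternary-complex
network needs: dense linear algebra, elementwise nonlinearities, softmax
attention, gather/segment operations, and reductions.  Arrays are float64
throughout; gradients follow numpy broadcasting rules.

The public surface is the :class:`Tensor` class plus a handful of free
functions (:func:`concatenate`, :func:`softmax`, ...).  A ``Tensor`` wraps a
``numpy.ndarray`` and records its parents so that :meth:`Tensor.backward`
can run a topological sweep accumulating ``grad`` on every tensor that
``requires_grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "softmax",
    "relu",
    "tanh",
    "exp",
    "log",
    "sqrt",
    "softplus",
    "abs_",
    "maximum_const",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # Sum over leading axes that broadcasting added.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Sum over axes that were size-1 in the original.
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, prev, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), lambda g: _route(g, (self, other), backward))

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._make(out_data, (self, other), lambda g: _route(g, (self, other), backward))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other._recip()

    def __rtruediv__(self, other):
        return as_tensor(other) * self._recip()

    def _recip(self):
        out_data = 1.0 / self.data

        def backward(g):
            return (_unbroadcast(-g / (self.data ** 2), self.data.shape),)

        return Tensor._make(out_data, (self,), lambda g: _route(g, (self,), backward))

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return (_unbroadcast(g * p * self.data ** (p - 1), self.data.shape),)

        return Tensor._make(out_data, (self,), lambda g: _route(g, (self,), backward))

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ other.data.swapaxes(-1, -2)
            gb = self.data.swapaxes(-1, -2) @ g
            return (_unbroadcast(ga, self.data.shape), _unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), lambda g: _route(g, (self, other), backward))

    # -- shape ops ------------------------------------------------------------
    @property
    def T(self):
        out_data = self.data.T

        def backward(g):
            return (g.T,)

        return Tensor._make(out_data, (self,), lambda g: _route(g, (self,), backward))

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = tuple(int(np.argsort(axes)[i]) for i in range(len(axes)))
        out_data = self.data.transpose(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._make(out_data, (self,), lambda g: _route(g, (self,), backward))

    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            return (g.reshape(orig),)

        return Tensor._make(out_data, (self,), lambda g: _route(g, (self,), backward))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            gi = np.zeros_like(self.data)
            np.add.at(gi, idx, g)
            return (gi,)

        return Tensor._make(out_data, (self,), lambda g: _route(g, (self,), backward))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                gi = np.broadcast_to(g, self.data.shape).copy()
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                gi = np.broadcast_to(g2, self.data.shape).copy()
            return (gi,)

        return Tensor._make(out_data, (self,), lambda g: _route(g, (self,), backward))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autograd driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._prev:
                    stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg


def _route(g, parents, backward):
    """Pair each requires_grad parent with its gradient contribution."""
    pgs = backward(g)
    return [(p, pg) for p, pg in zip(parents, pgs) if p.requires_grad]


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities ------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def backward(g):
        return ((g * (x.data > 0.0)),)

    return Tensor._make(out_data, (x,), lambda g: _route(g, (x,), backward))


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        return (g * (1.0 - out_data ** 2),)

    return Tensor._make(out_data, (x,), lambda g: _route(g, (x,), backward))


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def backward(g):
        return (g * out_data,)

    return Tensor._make(out_data, (x,), lambda g: _route(g, (x,), backward))


def log(x: Tensor) -> Tensor:
    out_data = np.log(x.data)

    def backward(g):
        return (g / x.data,)

    return Tensor._make(out_data, (x,), lambda g: _route(g, (x,), backward))


def sqrt(x: Tensor) -> Tensor:
    return x ** 0.5


def softplus(x: Tensor) -> Tensor:
    """Numerically stable log(1 + e^x)."""
    out_data = np.logaddexp(0.0, x.data)

    def backward(g):
        z = x.data
        sig = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                       1.0 - 1.0 / (1.0 + np.exp(-np.abs(z))))
        return (g * sig,)

    return Tensor._make(out_data, (x,), lambda g: _route(g, (x,), backward))


def abs_(x: Tensor) -> Tensor:
    out_data = np.abs(x.data)

    def backward(g):
        return (g * np.sign(x.data),)

    return Tensor._make(out_data, (x,), lambda g: _route(g, (x,), backward))


def maximum_const(x: Tensor, c: float) -> Tensor:
    """max(x, c) with a constant; subgradient flows where x > c."""
    out_data = np.maximum(x.data, c)

    def backward(g):
        return (g * (x.data > c),)

    return Tensor._make(out_data, (x,), lambda g: _route(g, (x,), backward))


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        slicer = [slice(None)] * g.ndim
        grads = []
        for i in range(len(tensors)):
            slicer[axis] = slice(offsets[i], offsets[i + 1])
            grads.append(g[tuple(slicer)])
        return tuple(grads)

    return Tensor._make(out_data, tuple(tensors), lambda g: _route(g, tuple(tensors), backward))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-stochastic softmax; the max-shift uses a detached constant."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = exp(x - Tensor(shift))
    return e / e.sum(axis=axis, keepdims=True)
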