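"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small (a few hundred thousand float64
parameters) and runs on CPU, so a compact tape-based engine is all that is
needed: every op records its parents and a closure that maps the output
gradient to parent gradients; :meth:`Tensor.backward` walks the tape in
reverse topological order.

All ops support numpy broadcasting on leading axes; gradients are summed
back to the parent's shape (``_unbroadcast``), which is what lets one
forward pass run over a whole minibatch of subjects stacked on axis 0.
Everything is float64: determinism and finite-difference gradient checks
matter more here than speed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Reduce ``grad`` (shape produced by broadcasting) back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: Array | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[Array], None] | None = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs here can be a few thousand nodes deep
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
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if not (parent.requires_grad or parent._backward is not None):
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def swap_last(self):
        return swapaxes(self, -1, -2)

    def __getitem__(self, idx):
        return getitem(self, idx)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: Array, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._backward is not None for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ------------------------------------------------------------------ primitives
def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

    return _node(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.shape)),
            (b, _unbroadcast(g * a.data, b.shape)),
        )

    return _node(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

    return _node(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = _wrap(a)
    data = a.data**exponent

    def backward(g):
        return ((a, g * exponent * a.data ** (exponent - 1.0)),)

    return _node(data, (a,), backward)


def exp(a) -> Tensor:
    a = _wrap(a)
    data = np.exp(a.data)

    def backward(g):
        return ((a, g * data),)

    return _node(data, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)
    data = np.log(a.data)

    def backward(g):
        return ((a, g / a.data),)

    return _node(data, (a,), backward)


def sqrt(a) -> Tensor:
    a = _wrap(a)
    data = np.sqrt(a.data)

    def backward(g):
        return ((a, g * 0.5 / data),)

    return _node(data, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        return ((a, g * mask),)

    return _node(data, (a,), backward)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    data = np.where(mask, a.data, slope * a.data)

    def backward(g):
        return ((a, g * np.where(mask, 1.0, slope)),)

    return _node(data, (a,), backward)


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
    data = np.where(mask, a.data, neg)

    def backward(g):
        return ((a, g * np.where(mask, 1.0, neg + alpha)),)

    return _node(data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g, a.shape).copy()),)

    return _node(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax primitive."""
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        inner = (g * data).sum(axis=axis, keepdims=True)
        return ((a, data * (g - inner)),)

    return _node(data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    old = a.shape
    data = a.data.reshape(shape)

    def backward(g):
        return ((a, g.reshape(old)),)

    return _node(data, (a,), backward)


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = _wrap(a)
    data = np.swapaxes(a.data, ax1, ax2)

    def backward(g):
        return ((a, np.swapaxes(g, ax1, ax2)),)

    return _node(data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(zip(ts, pieces))

    return _node(data, ts, backward)


def getitem(a, idx) -> Tensor:
    a = _wrap(a)
    data = a.data[idx]

    def backward(g):
        full = np.zeros(a.shape)
        np.add.at(full, idx, g)
        return ((a, full),)

    return _node(data, (a,), backward)


def where_mask(mask: Array, a, fill: float) -> Tensor:
    """``a`` where ``mask`` else the constant ``fill`` (mask not differentiated)."""
    a = _wrap(a)
    data = np.where(mask, a.data, fill)

    def backward(g):
        return ((a, np.where(mask, g, 0.0)),)

    return _node(data, (a,), backward)


def logsumexp(a, axis: int = -1, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    m = a.data.max(axis=axis, keepdims=True)  # constant shift: exact gradient
    out = log(tsum(exp(add(a, Tensor(-m))), axis=axis, keepdims=True)) + Tensor(m)
    if not keepdims:
        out = reshape(out, np.squeeze(out.data, axis=axis).shape)
    return out
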