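"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the models in this package: broadcasting
elementwise arithmetic, (batched) matmul, GELU/sigmoid/softmax, reductions,
indexing/embedding lookup, stacking and reshaping.  Gradients are
accumulated by a topological backward sweep from a scalar loss.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "no_grad", "stack", "concat", "relu", "grad_enabled"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and grad_enabled()
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- infrastructure ------------------------------------------------------

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

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._parents
                       if p.requires_grad and id(p) not in seen]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _accumulate(t: "Tensor", g: np.ndarray) -> None:
        # grads are never mutated in place, so sharing the incoming array is safe
        if t.grad is None:
            t.grad = g
        else:
            t.grad = t.grad + g

    # -- elementwise arithmetic ---------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                Tensor._accumulate(self, _unbroadcast(g, self.shape))
            if other.requires_grad:
                Tensor._accumulate(other, _unbroadcast(g, other.shape))
        return Tensor(out_data, req, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            Tensor._accumulate(self, -g)
        return Tensor(-self.data, self.requires_grad, (self,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                Tensor._accumulate(self, _unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                Tensor._accumulate(other, _unbroadcast(g * self.data, other.shape))
        return Tensor(out_data, req, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            Tensor._accumulate(self, g * p * self.data ** (p - 1))
        return Tensor(out_data, self.requires_grad, (self,), bw)

    # -- linear algebra ------------------------------------------------------

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data
        req = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                Tensor._accumulate(self, _unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                Tensor._accumulate(other, _unbroadcast(gb, other.shape))
        return Tensor(out_data, req, (self, other), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            Tensor._accumulate(self, np.swapaxes(g, a, b))
        return Tensor(np.swapaxes(self.data, a, b),
                      self.requires_grad, (self,), bw)

    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            Tensor._accumulate(self, g.reshape(old))
        return Tensor(self.data.reshape(*shape), self.requires_grad, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            Tensor._accumulate(self, full)
        return Tensor(out_data, self.requires_grad, (self,), bw)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                Tensor._accumulate(self, np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            Tensor._accumulate(self, np.broadcast_to(gg, self.shape).copy())
        return Tensor(out_data, self.requires_grad, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            Tensor._accumulate(self, g * out_data)
        return Tensor(out_data, self.requires_grad, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            Tensor._accumulate(self, g / self.data)
        return Tensor(out_data, self.requires_grad, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            Tensor._accumulate(self, g * out_data * (1.0 - out_data))
        return Tensor(out_data, self.requires_grad, (self,), bw)

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out_data = x * cdf
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def bw(g):
            Tensor._accumulate(self, g * (cdf + x * pdf))
        return Tensor(out_data, self.requires_grad, (self,), bw)

    def softmax(self, axis: int = -1, mask: np.ndarray | None = None):
        """Stable softmax; ``mask`` (same shape, 0/-inf) is added to logits."""
        z = self.data if mask is None else self.data + mask
        z = z - z.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            Tensor._accumulate(self, out_data * (g - dot))
        return Tensor(out_data, self.requires_grad, (self,), bw)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(t: Tensor) -> Tensor:
    mask = (t.data > 0).astype(np.float64)

    def bw(g):
        Tensor._accumulate(t, g * mask)
    return Tensor(t.data * mask, t.requires_grad, (t,), bw)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out_data = np.stack([t.data for t in ts], axis=axis)
    req = any(t.requires_grad for t in ts)

    def bw(g):
        parts = np.split(g, len(ts), axis=axis)
        for t, p in zip(ts, parts):
            if t.requires_grad:
                Tensor._accumulate(t, np.squeeze(p, axis=axis))
    return Tensor(out_data, req, tuple(ts), bw)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    req = any(t.requires_grad for t in ts)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                Tensor._accumulate(t, g[tuple(sl)])
    return Tensor(out_data, req, tuple(ts), bw)
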