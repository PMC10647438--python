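"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

The networks in this package are modest (a few hundred coarse-grained array
operations per forward pass), so a tape of NumPy ops with per-op backward
closures is both fast enough on one CPU and fully transparent: gradients of
any intermediate tensor are retained after ``backward()``, which is what the
saliency-mapping code needs.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _needs_graph(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=grad.dtype if
                                      np.issubdtype(grad.dtype, np.floating) else np.float64)
        self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor through the recorded graph.

        Gradients are retained on every visited node (``.grad``), including
        intermediates — callers such as Grad-CAM rely on this.
        """
        if grad is None:
            grad = np.ones_like(self.data, dtype=np.result_type(self.data, np.float32))
        # iterative topological sort (graphs can be a few hundred nodes deep)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p._needs_graph():
                    stack.append((p, False))
        self.accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._backward is _PENDING:
            def bw(g):
                _acc(self, _unbroadcast(g, self.shape))
                _acc(other, _unbroadcast(g, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: _acc(self, -g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._backward is _PENDING:
            def bw(g):
                _acc(self, _unbroadcast(g * other.data, self.shape))
                _acc(other, _unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out._backward is _PENDING:
            def bw(g):
                _acc(self, _unbroadcast(g / other.data, self.shape))
                _acc(other, _unbroadcast(-g * self.data / other.data ** 2, other.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = _make(self.data ** exponent, (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: _acc(self, g * exponent * self.data ** (exponent - 1))
        return out

    # -- reductions and transcendental ops --------------------------------

    def sum(self):
        out = _make(self.data.sum(), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: _acc(self, np.broadcast_to(g, self.shape).copy())
        return out

    def mean(self):
        n = self.data.size
        return self.sum() / n

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: _acc(self, g / self.data)
        return out

    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: _acc(self, g * out.data)
        return out

    def sigmoid(self):
        x = self.data
        y = np.empty_like(x, dtype=np.result_type(x, np.float32))
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        out = _make(y, (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: _acc(self, g * y * (1.0 - y))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the bounds."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: _acc(self, g * inside)
        return out

    def reshape(self, *shape):
        orig = self.shape
        out = _make(self.data.reshape(*shape), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: _acc(self, g.reshape(orig))
        return out

    def take_channels(self, idx: Iterable[int]):
        """Select input channels from a (N, C, X, Y, Z) tensor."""
        idx = list(idx)
        out = _make(self.data[:, idx], (self,))
        if out._backward is _PENDING:
            def bw(g):
                full = np.zeros_like(self.data, dtype=g.dtype)
                full[:, idx] = g
                _acc(self, full)
            out._backward = bw
        return out


class Parameter(Tensor):
    """A leaf tensor optimized during training."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


_PENDING = object()  # sentinel: backward closure still to be attached


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    """Create an op output; records the graph only when needed."""
    if _grad_enabled and any(p._needs_graph() for p in parents):
        out = Tensor(data, parents=parents)
        out._backward = _PENDING  # type: ignore[assignment]
        return out
    return Tensor(data)


def _acc(t: Tensor, g: np.ndarray) -> None:
    if t._needs_graph():
        t.accumulate(g)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._backward is _PENDING:
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                _acc(t, g[tuple(sl)])
        out._backward = bw
    return out
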