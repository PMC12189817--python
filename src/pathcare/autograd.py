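"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package are small (two GRU encoders, a handful of
linear maps and element-wise gates), so a compact tape-based engine is
sufficient: every operation records a closure that propagates the upstream
gradient to its inputs, and :meth:`Tensor.backward` walks the tape in
reverse topological order.

Only the operations the model needs are implemented.  Gradients are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    # -- graph construction -------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the tape
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: ArrayLike | "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def _bw(g: np.ndarray) -> None:
                if self.requires_grad:
                    self._accumulate(g)
                if other.requires_grad:
                    other._accumulate(g)

            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: ArrayLike | "Tensor") -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other: ArrayLike | "Tensor") -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other: ArrayLike | "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def _bw(g: np.ndarray) -> None:
                if self.requires_grad:
                    self._accumulate(g * other.data)
                if other.requires_grad:
                    other._accumulate(g * self.data)

            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        return self * (1.0 / float(other))

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g: np.ndarray) -> None:
                self._accumulate(g * p * self.data ** (p - 1))

            out._backward = _bw
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def _bw(g: np.ndarray) -> None:
                if self.requires_grad:
                    self._accumulate(g @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ g)

            out._backward = _bw
        return out

    # -- reductions and shapes ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            shape = self.data.shape

            def _bw(g: np.ndarray) -> None:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, shape))

            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g: np.ndarray) -> None:
                self._accumulate(g.T)

            out._backward = _bw
        return out

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            orig = self.data.shape

            def _bw(g: np.ndarray) -> None:
                self._accumulate(g.reshape(orig))

            out._backward = _bw
        return out

    # -- nonlinearities ------------------------------------------------
    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g: np.ndarray) -> None:
                self._accumulate(g * y * (1.0 - y))

            out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g: np.ndarray) -> None:
                self._accumulate(g * (1.0 - y * y))

            out._backward = _bw
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g: np.ndarray) -> None:
                self._accumulate(g * y)

            out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g: np.ndarray) -> None:
                self._accumulate(g / self.data)

            out._backward = _bw
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is passed through only inside the range."""
        y = np.clip(self.data, lo, hi)
        out = Tensor(y, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            inside = (self.data > lo) & (self.data < hi)

            def _bw(g: np.ndarray) -> None:
                self._accumulate(g * inside)

            out._backward = _bw
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        x = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(x)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g: np.ndarray) -> None:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate(y * (g - dot))

            out._backward = _bw
        return out

    def cumsum(self, axis: int = -1) -> "Tensor":
        out = Tensor(np.cumsum(self.data, axis=axis), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g: np.ndarray) -> None:
                # adjoint of cumsum is a reversed cumsum
                rev = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis),
                              axis=axis)
                self._accumulate(rev)

            out._backward = _bw
        return out


def as_tensor(x: ArrayLike | Tensor) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g: np.ndarray) -> None:
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = _bw
    return out


def zero_grads(tensors: Sequence[Tensor]) -> None:
    for t in tensors:
        t.grad = None
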