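"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the compute core behind the network: a :class:`Tensor` wrapping an
``ndarray``, a closed set of differentiable primitives (matmul, softmax,
sigmoid/tanh/relu, reductions, concat/slice, embedding gather), a topological
backward pass, and an Adam optimizer.  Everything runs in float64 on a single
CPU thread, which makes full training runs bit-reproducible under a fixed
seed.

Only the operations the model needs are implemented; shapes are validated by
NumPy broadcasting plus explicit checks where silent broadcasting would hide
a bug.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_accumulate")

    # make `ndarray <op> Tensor` defer to the Tensor reflected operators
    # instead of producing an object array
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs can be deep (unrolled GRU)
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                node._accumulate = grads  # type: ignore[attr-defined]
                node._backward(g)
                del node._accumulate  # type: ignore[attr-defined]

    def _send(self, parent: "Tensor", grad: np.ndarray) -> None:
        if not parent.requires_grad:
            return
        acc = self._accumulate  # type: ignore[attr-defined]
        key = id(parent)
        if key in acc:
            acc[key] = acc[key] + grad
        else:
            acc[key] = grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._node(self.data + other.data, (self, other), None)
        out._backward = lambda g: (
            out._send(self, _unbroadcast(g, self.shape)),
            out._send(other, _unbroadcast(g, other.shape)),
        ) and None
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = self._node(-self.data, (self,), None)
        out._backward = lambda g: out._send(self, -g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._node(self.data * other.data, (self, other), None)
        out._backward = lambda g: (
            out._send(self, _unbroadcast(g * other.data, self.shape)),
            out._send(other, _unbroadcast(g * self.data, other.shape)),
        ) and None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._node(self.data / other.data, (self, other), None)
        out._backward = lambda g: (
            out._send(self, _unbroadcast(g / other.data, self.shape)),
            out._send(other, _unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape)),
        ) and None
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = self._node(self.data ** exponent, (self,), None)
        out._backward = lambda g: out._send(
            self, g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        if self.ndim < 2 or other.ndim < 2:
            raise ValueError("matmul operands must be at least 2-D")
        out = self._node(self.data @ other.data, (self, other), None)

        def backward(g: np.ndarray) -> None:
            out._send(self, _unbroadcast(g @ other.data.swapaxes(-1, -2),
                                         self.shape))
            out._send(other, _unbroadcast(self.data.swapaxes(-1, -2) @ g,
                                          other.shape))

        out._backward = backward
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self) -> "Tensor":
        data = np.exp(self.data)
        out = self._node(data, (self,), None)
        out._backward = lambda g: out._send(self, g * data)
        return out

    def log(self) -> "Tensor":
        out = self._node(np.log(self.data), (self,), None)
        out._backward = lambda g: out._send(self, g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        data = np.sqrt(self.data)
        out = self._node(data, (self,), None)
        out._backward = lambda g: out._send(self, g * 0.5 / data)
        return out

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)
        out = self._node(data, (self,), None)
        out._backward = lambda g: out._send(self, g * (1.0 - data ** 2))
        return out

    def sigmoid(self) -> "Tensor":
        data = 1.0 / (1.0 + np.exp(-self.data))
        out = self._node(data, (self,), None)
        out._backward = lambda g: out._send(self, g * data * (1.0 - data))
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = self._node(self.data * mask, (self,), None)
        out._backward = lambda g: out._send(self, g * mask)
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is passed through inside the interval."""
        mask = (self.data > lo) & (self.data < hi)
        out = self._node(np.clip(self.data, lo, hi), (self,), None)
        out._backward = lambda g: out._send(self, g * mask)
        return out

    def maximum(self, floor: float) -> "Tensor":
        """Elementwise max(x, floor); subgradient 0 at the hinge."""
        mask = self.data > floor
        out = self._node(np.maximum(self.data, floor), (self,), None)
        out._backward = lambda g: out._send(self, g * mask)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        data = e / e.sum(axis=axis, keepdims=True)
        out = self._node(data, (self,), None)
        out._backward = lambda g: out._send(
            self, data * (g - (g * data).sum(axis=axis, keepdims=True)))
        return out

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g: np.ndarray) -> None:
            if axis is None:
                out._send(self, np.broadcast_to(g, shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                out._send(self, np.broadcast_to(gg, shape).copy())

        out = self._node(data, (self,), None)
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        orig = self.shape
        out = self._node(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: out._send(self, g.reshape(orig))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = self._node(self.data.swapaxes(a, b), (self,), None)
        out._backward = lambda g: out._send(self, g.swapaxes(a, b))
        return out

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]
        shape = self.shape

        def backward(g: np.ndarray) -> None:
            full = np.zeros(shape)
            np.add.at(full, idx, g)
            out._send(self, full)

        out = self._node(data, (self,), None)
        out._backward = backward
        return out

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Embedding-style gather: rows of a (V, d) table by integer index."""
        idx = np.asarray(indices)
        data = self.data[idx]
        shape = self.shape

        def backward(g: np.ndarray) -> None:
            full = np.zeros(shape)
            np.add.at(full, idx.reshape(-1), g.reshape(-1, shape[-1]))
            out._send(self, full)

        out = self._node(data, (self,), None)
        out._backward = backward
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Differentiable concatenation along `axis`."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            out._send(t, piece)

    out = Tensor._node(data, tensors, None)
    out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Differentiable stack along a new axis."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g: np.ndarray) -> None:
        for i, t in enumerate(tensors):
            out._send(t, np.take(g, i, axis=axis))

    out = Tensor._node(data, tensors, None)
    out._backward = backward
    return out


class Adam:
    """Adam optimizer over named parameter tensors.

    `step` updates only parameters whose name passes `trainable`; the first-
    and second-moment state of the untouched parameters is left untouched as
    well, so a frozen module's parameters are bit-identical before and after
    the phase in which it is frozen.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = {k: 0 for k in params}

    def step(self, trainable: Callable[[str], bool] | None = None,
             lr: float | None = None) -> None:
        rate = self.lr if lr is None else lr
        for name, p in self.params.items():
            if p.grad is None:
                continue
            if trainable is not None and not trainable(name):
                continue
            self.t[name] += 1
            t = self.t[name]
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * p.grad
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * p.grad ** 2
            m_hat = self.m[name] / (1 - self.b1 ** t)
            v_hat = self.v[name] / (1 - self.b2 ** t)
            p.data = p.data - rate * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
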