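"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides exactly the operations the scoring networks and
training loops need: broadcasting arithmetic, (batched) matrix products,
pointwise nonlinearities, reductions, table lookup (embedding gather) and
a conditional select. Gradients are accumulated on a tape and released by
:meth:`Tensor.backward`; correctness is established in the test suite by
central-difference checks on every primitive and on full model forwards.

All arrays are float64. The engine is deliberately eager and single
threaded: determinism of a training run therefore reduces to determinism
of numpy itself under a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]

__all__ = ["Tensor", "constant", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size 1 in the original
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(x: Union["Tensor", ArrayLike]) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(parents)
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        a = self

        def backward(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1))

        return self._make(a.data ** exponent, (a,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2) if b.data.ndim > 1 else np.outer(g, b.data)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                if a.data.ndim == 1:
                    gb = np.outer(a.data, g)
                else:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return self._make(out_data, (a, b), backward)

    # -- nonlinearities ------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accumulate(g * (1.0 - out_data * out_data))

        return self._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = _sigmoid(a.data)

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    def softplus(self):
        """Overflow-safe ln(1 + e^x); derivative is the logistic function."""
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def backward(g):
            a._accumulate(g * _sigmoid(a.data))

        return self._make(out_data, (a,), backward)

    def shifted_softplus(self):
        """ssp(x) = ln(0.5 e^x + 0.5) = softplus(x) - ln 2, with ssp(0) = 0."""
        a = self
        out_data = np.logaddexp(0.0, a.data) - np.log(2.0)

        def backward(g):
            a._accumulate(g * _sigmoid(a.data))

        return self._make(out_data, (a,), backward)

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                grad = np.broadcast_to(g, a.shape)
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                grad = np.broadcast_to(g, a.shape)
            a._accumulate(grad.astype(np.float64))

        return self._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            a._accumulate(g.reshape(a.shape))

        return self._make(a.data.reshape(shape), (a,), backward)

    def take(self, indices: np.ndarray):
        """Row lookup along axis 0 (embedding gather)."""
        a = self
        idx = np.asarray(indices)

        def backward(g):
            grad = np.zeros_like(a.data)
            np.add.at(grad, idx.reshape(-1), g.reshape(-1, *a.shape[1:]))
            a._accumulate(grad)

        return self._make(a.data[idx], (a,), backward)

    def where(self, cond: np.ndarray, other: Union["Tensor", ArrayLike]):
        """Elementwise select: cond ? self : other (cond is constant)."""
        other = self._wrap(other)
        a, b = self, other
        cond = np.asarray(cond, dtype=bool)
        out_data = np.where(cond, a.data, b.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(np.where(cond, g, 0.0), a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(np.where(cond, 0.0, g), b.shape))

        return self._make(out_data, (a, b), backward)

    def clip(self, lo: float, hi: float):
        a = self
        out_data = np.clip(a.data, lo, hi)
        inside = (a.data > lo) & (a.data < hi)

        def backward(g):
            a._accumulate(np.where(inside, g, 0.0))

        return self._make(out_data, (a,), backward)

    # -- backward pass -------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this node through the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(node: Tensor) -> None:
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def constant(data: ArrayLike) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data: ArrayLike) -> Tensor:
    return Tensor(data, requires_grad=True)
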