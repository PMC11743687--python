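"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operator set the variational model needs: broadcasting
arithmetic, matmul, elementwise transcendentals, reductions, row gathering,
and a hook for custom primitives (the B-spline layer registers one). The
engine is deliberately small: a :class:`Tensor` records its parents and a
backward closure; :meth:`Tensor.backward` runs a topological sweep.

Gradients are validated against central finite differences in the test
suite; do not add an op without a corresponding gradient check.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "sigmoid", "silu", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(_unbroadcast(
                -g * self.data / other.data ** 2, other.data.shape))

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data ** exponent, parents=(self,), backward=bwd)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    # -- elementwise ----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor(out_data, parents=(self,), backward=bwd)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- structure ------------------------------------------------------
    @property
    def T(self):
        def bwd(g):
            self._accumulate(g.T)

        return Tensor(self.data.T, parents=(self,), backward=bwd)

    def take_rows(self, idx):
        """Gather rows (fancy index along axis 0); scatter-add on backward."""
        idx = np.asarray(idx, dtype=np.intp)

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accumulate(acc)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    def reshape(self, *shape):
        def bwd(g):
            self._accumulate(g.reshape(self.data.shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def detach(self) -> np.ndarray:
        return self.data.copy()

    # -- custom primitives ---------------------------------------------
    @staticmethod
    def from_op(out_data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        """Register a custom primitive with an explicit backward closure."""
        return Tensor(out_data, parents=parents, backward=backward)

    # -- engine ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs would blow the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def sigmoid(x: Tensor) -> Tensor:
    """Numerically stable logistic function."""
    out_data = np.where(x.data >= 0,
                        1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500))),
                        np.exp(np.clip(x.data, -500, 500))
                        / (1.0 + np.exp(np.clip(x.data, -500, 500))))

    def bwd(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor.from_op(out_data, (x,), bwd)


def silu(x: Tensor) -> Tensor:
    """x * sigmoid(x) (the smooth gating used by the KAN base transform)."""
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out_data = x.data * s

    def bwd(g):
        x._accumulate(g * (s + x.data * s * (1.0 - s)))

    return Tensor.from_op(out_data, (x,), bwd)
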