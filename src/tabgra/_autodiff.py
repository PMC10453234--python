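"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the attentive/feature-transformer network in
:mod:`tabgra.tabnet`: elementwise arithmetic with broadcasting, matrix
multiplication, reductions, relu/sigmoid/sqrt/log, row slicing and
concatenation, and a sparsemax primitive with its exact Jacobian-vector
product.  Gradients are accumulated by topologically ordered backward
passes; every op's gradient is verified against finite differences in the
test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "cat_rows", "sparsemax_np"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)

            def _bw() -> None:
                backward(out.grad)

            out._backward = _bw
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (many epochs of blocks)
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
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- elementwise arithmetic --------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._coerce(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other) -> "Tensor":
        other = self._coerce(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions and nonlinearities --------------------------------------

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            grad = g
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accumulate(np.broadcast_to(grad, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def sqrt(self) -> "Tensor":
        root = np.sqrt(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * 0.5 / root)

        return self._make(root, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- shape ops -----------------------------------------------------------

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                grad[:, start:stop] = g
                self._accumulate(grad)

        return self._make(self.data[:, start:stop], (self,), backward)

    def slice_rows(self, start: int, stop: int) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                grad[start:stop] = g
                self._accumulate(grad)

        return self._make(self.data[start:stop], (self,), backward)

    # -- sparsemax -----------------------------------------------------------

    def sparsemax(self, support: np.ndarray | None = None) -> "Tensor":
        """Row-wise Euclidean projection onto the probability simplex.

        ``support`` (optional boolean mask, same shape) restricts the
        projection to the marked coordinates; excluded coordinates get
        exactly zero output and zero gradient.
        """
        p = sparsemax_np(self.data, support)
        in_support = p > 0

        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            # Jacobian of the projection: on the active support S,
            # dz = g - mean_S(g); elsewhere 0.
            masked = np.where(in_support, g, 0.0)
            counts = in_support.sum(axis=-1, keepdims=True)
            mean_on_support = masked.sum(axis=-1, keepdims=True) / np.maximum(counts, 1)
            self._accumulate(np.where(in_support, g - mean_on_support, 0.0))

        return self._make(p, (self,), backward)

    def detach(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def cat_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate tensors along axis 0, routing gradients back to each block."""
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=0)
    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        offsets = np.cumsum([0] + [t.data.shape[0] for t in tensors])

        def _bw() -> None:
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    t._accumulate(out.grad[lo:hi])

        out._backward = _bw
    return out


def sparsemax_np(z: np.ndarray, support: np.ndarray | None = None) -> np.ndarray:
    """Row-wise sparsemax (Euclidean projection onto the simplex), pure numpy.

    Sorted-threshold algorithm: with z sorted descending, the support size is
    the largest j such that 1 + j*z_(j) > sum of the top-j entries; the
    threshold tau is (sum of supported entries - 1) / |support|, and the
    output is max(z - tau, 0).  An optional boolean ``support`` mask limits
    the projection to a subset of coordinates; rows whose mask is empty fall
    back to the full coordinate set.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("sparsemax received non-finite input")
    squeeze = z.ndim == 1
    if squeeze:
        z = z[np.newaxis, :]
    if support is not None:
        support = np.broadcast_to(np.asarray(support, dtype=bool), z.shape)
        empty = ~support.any(axis=-1, keepdims=True)
        support = support | empty  # degenerate all-excluded rows: use every coordinate
        # push excluded coordinates far below every real score so they never
        # enter the sorted support
        z = np.where(support, z, z.min() - 1.0 - (z.max() - z.min()))
    d = z.shape[-1]
    z_sorted = -np.sort(-z, axis=-1)
    cumsum = np.cumsum(z_sorted, axis=-1)
    ks = np.arange(1, d + 1)
    feasible = 1.0 + ks * z_sorted > cumsum
    k = feasible.sum(axis=-1, keepdims=True)  # support size >= 1 always
    tau = (np.take_along_axis(cumsum, k - 1, axis=-1) - 1.0) / k
    p = np.maximum(z - tau, 0.0)
    if support is not None:
        p = np.where(support, p, 0.0)
    # rescale away the last-ulp rounding of tau so a fully selected coordinate
    # is exactly 1 (zero entries are unaffected); sums stay 1 to working precision
    p = p / p.sum(axis=-1, keepdims=True)
    return p[0] if squeeze else p
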