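"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in :mod:`cid_rpcnn.model` is small (a few hundred thousand
parameters) and all heavy lifting happens inside batched numpy matmuls, so a
compact tape-based engine is sufficient: each :class:`Tensor` records the
operation that produced it and a closure that routes the upstream gradient to
its parents.  ``float64`` is used throughout so that analytic gradients can be
checked against central finite differences to tight tolerances.

Only the operations the model needs are implemented.  Broadcasting in
elementwise ops is supported; the backward pass sums gradients over broadcast
axes (:func:`_unbroadcast`).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were prepended
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a ``float64`` ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        arr = np.asarray(data)
        # float32 is honoured (training speed); everything else promotes to
        # float64, the default and the dtype gradient checks rely on
        self.data = arr if arr.dtype == np.float32 else np.asarray(arr, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    # -- graph mechanics ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | float | None = None) -> None:
        """Run reverse-mode accumulation from this node."""
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort (graphs can be deep: LSTM)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = np.empty_like(self.data)
        pos = self.data >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        e = np.exp(self.data[~pos])
        y[~pos] = e / (1.0 + e)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        # basic (slice) indexing only: no duplicate positions, so plain
        # in-place add is a correct scatter
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] += g
            self._accumulate(full)

        out._backward = bwd
        return out

    def take_rows(self, indices: np.ndarray):
        """Row gather (embedding lookup); backward scatter-adds."""
        idx = np.asarray(indices)
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx.reshape(-1), g.reshape(-1, self.data.shape[-1]))
            self._accumulate(full)

        out._backward = bwd
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def masked_max(self, mask: np.ndarray, axis: int):
        """Max over ``axis`` restricted to ``mask==1``; 0 where mask is empty.

        Gradient flows to the (first) argmax of each reduced slice; slices
        with an all-zero mask receive no gradient, matching the convention
        that an empty pooling segment contributes a zero feature.
        """
        mask = np.asarray(mask, dtype=bool)
        neg = np.where(mask, self.data, -np.inf)
        raw = neg.max(axis=axis)
        any_valid = mask.any(axis=axis)
        val = np.where(any_valid, raw, 0.0)
        arg = neg.argmax(axis=axis)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            idx = list(np.indices(val.shape))
            idx.insert(axis, arg)
            full[tuple(idx)] = np.where(any_valid, g, 0.0)
            self._accumulate(full)

        out._backward = bwd
        return out

    def masked_softmax(self, mask: np.ndarray, axis: int):
        """Softmax over ``axis`` restricted to ``mask==1``.

        Masked-out entries get probability 0; a slice whose mask is entirely
        zero yields an all-zero distribution (empty-segment convention).
        """
        mask = np.asarray(mask, dtype=bool)
        neg = np.where(mask, self.data, -np.inf)
        m = neg.max(axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.where(mask, np.exp(neg - m), 0.0)
        denom = e.sum(axis=axis, keepdims=True)
        a = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
        out = Tensor(a, parents=(self,))

        def bwd(g):
            # d softmax: a * (g - sum(g*a))
            inner = (g * a).sum(axis=axis, keepdims=True)
            self._accumulate(a * (g - inner))

        out._backward = bwd
        return out

    def bce_with_logits(self, targets: np.ndarray, weights: np.ndarray | None = None):
        """Mean binary cross-entropy of sigmoid(self) against targets.

        Computed in logit space: softplus(z) - y*z, numerically stable for
        large |z|.  Optional per-example weights (e.g. a positive-class
        weight) rescale each term before the mean.
        """
        z = self.data
        y = np.asarray(targets, dtype=np.float64)
        w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=np.float64)
        loss = w * (np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z))))
        out = Tensor(loss.mean(), parents=(self,))

        def bwd(g):
            s = np.empty_like(z)
            pos = z >= 0
            s[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
            e = np.exp(z[~pos])
            s[~pos] = e / (1.0 + e)
            self._accumulate(g * w * (s - y) / z.size)

        out._backward = bwd
        return out

    def dropout(self, p: float, rng: np.random.Generator, training: bool):
        """Inverted dropout; identity when not training or p == 0."""
        if not training or p <= 0.0:
            return self
        keep = ((rng.random(self.data.shape) >= p) / (1.0 - p)).astype(self.data.dtype)
        return self * Tensor(keep)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bwd
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = bwd
    return out
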