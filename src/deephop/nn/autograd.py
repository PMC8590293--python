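"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the resulting tape in reverse topological
order and accumulates gradients.  Only the operations the models in this
package need are implemented (dense/batched matmul, broadcasting arithmetic,
elementwise nonlinearities, reductions, gather/scatter, concatenation).

All floating point work is float32: model sizes here are small and float32
keeps BLAS throughput high on a single CPU core.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: tapes can be deep (GRU over atoms, decoding)
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
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.outer(g, other.data) if self.data.ndim == 2 else g[..., None] * other.data
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.outer(self.data, g)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bw
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accum(g * val * (1 - val))
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - val * val))
        return out

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(DTYPE))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).astype(DTYPE))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(inv))
        return out

    def take(self, indices, axis: int = 0):
        """Gather rows/slices by integer index (used for embeddings)."""
        idx = np.asarray(indices)
        out = Tensor(np.take(self.data, idx, axis=axis), self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if not self.requires_grad:
                return
            acc = np.zeros_like(self.data)
            if axis == 0:
                np.add.at(acc, idx, g)
            else:  # pragma: no cover - only axis 0 used by the models
                raise NotImplementedError
            self._accum(acc)
        out._backward = bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bw
    return out


def segment_sum(values: Tensor, segment_ids, n_segments: int) -> Tensor:
    """Scatter-add rows of `values` into `n_segments` output rows.

    The sum over an empty segment is the zero vector, matching the empty
    neighbourhood convention of the spatial message-passing layer.
    """
    ids = np.asarray(segment_ids)
    acc = np.zeros((n_segments,) + values.data.shape[1:], dtype=DTYPE)
    np.add.at(acc, ids, values.data)
    out = Tensor(acc, values.requires_grad)
    out._parents = (values,)
    out._backward = lambda g: values.requires_grad and values._accum(np.take(g, ids, axis=0))
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtract a stop-gradient max for stability; the constant shift has zero
    # gradient contribution so treating it as data is exact
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x - m
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()
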