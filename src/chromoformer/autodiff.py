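"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core the transformer modules are built on. It implements
a small tape-based autodiff: each :class:`Tensor` wraps a float64 ndarray and
remembers how it was produced, and :meth:`Tensor.backward` walks the tape in
reverse topological order accumulating gradients.

Only the operations the model needs are provided (broadcasted arithmetic,
batched matmul, softmax with additive masking, reductions, slicing, concat and
the usual elementwise nonlinearities). All computation is float64: the model
sizes involved are small and exact run-to-run reproducibility matters more
than speed here.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "no_grad_fixup"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _from_op(data: np.ndarray, prev: Iterable["Tensor"], backward) -> "Tensor":
        prev = tuple(p for p in prev if isinstance(p, Tensor))
        out = Tensor(data, requires_grad=any(p.requires_grad for p in prev))
        if out.requires_grad:
            out._prev = prev
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            return (-g,)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data * other.data
        a_data, b_data = self.data, other.data

        def backward(g):
            return (
                _unbroadcast(g * b_data, self.shape),
                _unbroadcast(g * a_data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data / other.data
        a_data, b_data = self.data, other.data

        def backward(g):
            return (
                _unbroadcast(g / b_data, self.shape),
                _unbroadcast(-g * a_data / (b_data * b_data), other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)
        a_data, b_data = self.data, other.data

        def backward(g):
            ga = np.matmul(g, np.swapaxes(b_data, -1, -2))
            gb = np.matmul(np.swapaxes(a_data, -1, -2), g)
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data**p
        a_data = self.data

        def backward(g):
            return (g * p * a_data ** (p - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            return (g.reshape(old),)

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def backward(g):
            return (np.swapaxes(g, a, b),)

        return Tensor._from_op(np.swapaxes(self.data, a, b), (self,), backward)

    @property
    def mT(self) -> "Tensor":
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]
        shape = self.shape

        def backward(g):
            full = np.zeros(shape, dtype=np.float64)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * s * (1.0 - s),)

        return Tensor._from_op(s, (self,), backward)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def backward(g):
            return (g * e,)

        return Tensor._from_op(e, (self,), backward)

    def log(self) -> "Tensor":
        a_data = self.data

        def backward(g):
            return (g / a_data,)

        return Tensor._from_op(np.log(a_data), (self,), backward)

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)

        def backward(g):
            return (g * 0.5 / r,)

        return Tensor._from_op(r, (self,), backward)

    def softmax(self) -> "Tensor":
        """Numerically stable softmax along the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=-1, keepdims=True)
            return (s * (g - dot),)

        return Tensor._from_op(s, (self,), backward)

    def layer_norm(self, eps: float = 1e-5) -> "Tensor":
        """Normalize the last axis to zero mean / unit variance (no affine)."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        n = self.shape[-1]

        def backward(g):
            gm = g.mean(axis=-1, keepdims=True)
            gym = (g * y).mean(axis=-1, keepdims=True)
            return (inv * (g - gm - y * gym),)

        return Tensor._from_op(y, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._prev, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    # views are safe: accumulation below always allocates anew
                    parent.grad = g if isinstance(g, np.ndarray) else np.asarray(g)
                else:
                    parent.grad = parent.grad + g


class Parameter(Tensor):
    """A trainable tensor (always tracks gradients)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def scatter_rows(src: Tensor, idx: np.ndarray, n_rows: int) -> Tensor:
    """Place rows of `src` at positions `idx` of an otherwise-zero output
    with ``n_rows`` leading rows (inverse of row selection)."""
    out_data = np.zeros((n_rows,) + src.shape[1:], dtype=np.float64)
    out_data[idx] = src.data

    def backward(g):
        return (g[idx],)

    return Tensor._from_op(out_data, (src,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else _as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(out_data, tensors, backward)


def no_grad_fixup(t: Tensor, data: np.ndarray) -> Tensor:
    """Replace `t`'s forward value without touching its backward closure.

    Used for forward-only corrections (e.g. the degenerate all-masked softmax
    row rule) that by construction never carry gradient in training.
    """
    t.data = np.asarray(data, dtype=np.float64)
    return t
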