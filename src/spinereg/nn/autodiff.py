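"""Minimal reverse-mode tensor autodiff on numpy arrays.

Supports exactly the operations the curvature-feature matcher needs: broadcast
arithmetic, matmul (batched), relu, exp/log/sqrt/pow, reductions, axis
permutation, reshape, concatenation, integer gathers and a fused softmax.
Gradients accumulate into ``Tensor.grad`` after calling ``backward()`` on a
scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "gather_rows"]


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
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -------------------------------------------------- plumbing
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))
        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)
        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))
        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        a = self
        out_data = a.data ** exponent

        def backward(g):
            a._accum(g * exponent * a.data ** (exponent - 1.0))
        return self._make(out_data, (a,), backward)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)
        return self._make(out_data, (a,), backward)

    def log(self) -> "Tensor":
        a = self

        def backward(g):
            a._accum(g / a.data)
        return self._make(np.log(a.data), (a,), backward)

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)
        return self._make(a.data * mask, (a,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))
        return self._make(a.data @ b.data, (a, b), backward)

    # -------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())
        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else (
            np.prod([self.shape[ax] for ax in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        # route gradient to the first occurrence of the max along the axis
        argmax = a.data.argmax(axis=axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            ga = np.zeros_like(a.data)
            np.put_along_axis(ga, np.expand_dims(argmax, axis), g, axis=axis)
            a._accum(ga)
        data = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return self._make(data, (a,), backward)

    # -------------------------------------------------- shape ops
    def reshape(self, *shape) -> "Tensor":
        a = self
        orig = a.shape

        def backward(g):
            a._accum(g.reshape(orig))
        return self._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes) -> "Tensor":
        a = self
        axes = axes or tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))
        return self._make(a.data.transpose(axes), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int) -> "Tensor":
        a = self

        def backward(g):
            a._accum(np.swapaxes(g, ax1, ax2))
        return self._make(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    def take(self, indices: np.ndarray) -> "Tensor":
        """Gather flat elements: out[k] = flat(self)[indices[k]]."""
        a = self
        idx = np.asarray(indices, dtype=np.intp)

        def backward(g):
            ga = np.zeros(a.data.size)
            np.add.at(ga, idx.ravel(), g.ravel())
            a._accum(ga.reshape(a.shape))
        return self._make(a.data.reshape(-1)[idx], (a,), backward)

    # -------------------------------------------------- fused softmax
    def softmax(self, axis: int = -1) -> "Tensor":
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))
        return self._make(out_data, (a,), backward)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        soft = np.exp(out_data)

        def backward(g):
            a._accum(g - soft * g.sum(axis=axis, keepdims=True))
        return self._make(out_data, (a,), backward)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = backward
    return out


def gather_rows(t: Tensor, indices: np.ndarray) -> Tensor:
    """out[..., :] = t[indices[...], :] — integer gather along axis 0.

    ``indices`` may have any shape; the result has shape
    ``indices.shape + t.shape[1:]``.
    """
    idx = np.asarray(indices, dtype=np.intp)

    def backward(g):
        ga = np.zeros_like(t.data)
        np.add.at(ga, idx.ravel(), g.reshape(-1, *t.shape[1:]))
        t._accum(ga)
    return t._make(t.data[idx], (t,), backward)
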