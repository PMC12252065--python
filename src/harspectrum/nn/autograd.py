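"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the operations the package's models and losses
need are implemented (elementwise arithmetic, matmul, reductions, relu,
exp/log/sqrt, concatenation/slicing, and the dedicated conv/pool/batch-norm
primitives in :mod:`harspectrum.nn.layers`).

Everything is computed in float64: the networks here are small and CPU-bound,
and double precision keeps the finite-difference gradient checks tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers to our __radd__ etc.

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _make(cls, value, parents, backward) -> "Tensor":
        out = cls(value)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def __float__(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.value)
        else:
            grad = np.asarray(grad, dtype=np.float64)

        # reverse topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                node.grad = pg_acc = (node.grad + g) if node.grad is not None else g
                del pg_acc

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = astensor(other)
        out = self.value + other.value

        def backward(g):
            return ((self, _unbroadcast(g, self.value.shape)),
                    (other, _unbroadcast(g, other.value.shape)))

        return Tensor._make(out, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return ((self, -g),)

        return Tensor._make(-self.value, (self,), backward)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = self.value * other.value

        def backward(g):
            return ((self, _unbroadcast(g * other.value, self.value.shape)),
                    (other, _unbroadcast(g * self.value, other.value.shape)))

        return Tensor._make(out, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = self.value / other.value

        def backward(g):
            return ((self, _unbroadcast(g / other.value, self.value.shape)),
                    (other, _unbroadcast(-g * self.value / other.value ** 2,
                                         other.value.shape)))

        return Tensor._make(out, (self, other), backward)

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        out = self.value ** p

        def backward(g):
            return ((self, g * p * self.value ** (p - 1)),)

        return Tensor._make(out, (self,), backward)

    def __matmul__(self, other):
        other = astensor(other)
        out = self.value @ other.value

        def backward(g):
            ga = g @ np.swapaxes(other.value, -1, -2)
            gb = np.swapaxes(self.value, -1, -2) @ g
            return ((self, _unbroadcast(ga, self.value.shape)),
                    (other, _unbroadcast(gb, other.value.shape)))

        return Tensor._make(out, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        mask = self.value > 0

        def backward(g):
            return ((self, g * mask),)

        return Tensor._make(self.value * mask, (self,), backward)

    def exp(self):
        out = np.exp(self.value)

        def backward(g):
            return ((self, g * out),)

        return Tensor._make(out, (self,), backward)

    def log(self):
        def backward(g):
            return ((self, g / self.value),)

        return Tensor._make(np.log(self.value), (self,), backward)

    def sqrt(self):
        out = np.sqrt(self.value)

        def backward(g):
            return ((self, g * 0.5 / out),)

        return Tensor._make(out, (self,), backward)

    # -- reductions and reshapes ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.value.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.value.shape).copy()),)

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.value.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.value.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis=None, keepdims: bool = False):
        """Reduction max; gradient flows to the first max position(s)."""
        out = self.value.max(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            full = out if keepdims or axis is None else np.expand_dims(out, axis)
            mask = (self.value == full)
            # split gradient over ties to keep the check symmetric
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            gg = g if keepdims or axis is None else np.expand_dims(g, axis)
            return ((self, mask * gg / counts),)

        return Tensor._make(out, (self,), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.value.shape

        def backward(g):
            return ((self, g.reshape(old)),)

        return Tensor._make(self.value.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or None

        def backward(g):
            inv = np.argsort(axes) if axes else None
            return ((self, g.transpose(inv) if inv is not None else g.transpose()),)

        return Tensor._make(self.value.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out = self.value[idx]

        def backward(g):
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor._make(out, (self,), backward)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor._make(out, tuple(tensors), backward)
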