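"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``backward()`` on a scalar result accumulates gradients into every reachable
tensor created with ``requires_grad=True``.  The op set is exactly what the
patch-masked transformer needs: broadcasting arithmetic, (batched) matmul,
reshape/transpose/slicing/concat, ReLU, softmax, layer norm, dropout and
reductions.  Everything runs in float64 for bit-reproducible training runs
at the problem sizes this package targets.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "layer_norm", "dropout", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (the inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    # -- construction helpers ---------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(grad, out):
            return (_unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(grad, out):
            return (
                _unbroadcast(grad * other.data, self.shape),
                _unbroadcast(grad * self.data, other.shape),
            )

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("division by a Tensor is not supported")
        return self * (1.0 / other)

    def square(self):
        def backward(grad, out):
            return (grad * 2.0 * self.data,)

        return Tensor._from_op(self.data**2, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def backward(grad, out):
            ga = grad @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ grad
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._from_op(a @ b, (self, other), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def backward(grad, out):
            return (grad.reshape(orig),)

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(grad, out):
            return (grad.transpose(*inv),)

        return Tensor._from_op(self.data.transpose(*axes), (self,), backward)

    def broadcast_to(self, shape):
        orig = self.shape

        def backward(grad, out):
            return (_unbroadcast(grad, orig),)

        return Tensor._from_op(np.broadcast_to(self.data, shape), (self,), backward)

    def index_last(self, idx):
        """Select columns ``idx`` (int array or slice) along the last axis."""
        orig = self.shape

        def backward(grad, out):
            full = np.zeros(orig)
            full[..., idx] = grad
            return (full,)

        return Tensor._from_op(self.data[..., idx], (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        orig = self.shape

        def backward(grad, out):
            if axis is None:
                return (np.broadcast_to(grad, orig).copy(),)
            g = grad
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, orig).copy(),)

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff ----------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(grad, out):
        return (grad * mask,)

    return Tensor._from_op(np.where(mask, x.data, 0.0), (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(grad, out):
        dot = (grad * y).sum(axis=axis, keepdims=True)
        return (y * (grad - dot),)

    return Tensor._from_op(y, (x,), backward)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    y = xhat * weight.data + bias.data
    d = x.data.shape[-1]

    def backward(grad, out):
        dxhat = grad * weight.data
        dx = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        axes = tuple(range(grad.ndim - 1))
        dw = (grad * xhat).sum(axis=axes)
        db = grad.sum(axis=axes)
        return (dx, dw, db)

    _ = d
    return Tensor._from_op(y, (x, weight, bias), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p == 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)

    def backward(grad, out):
        return (grad * keep,)

    return Tensor._from_op(x.data * keep, (x,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad, out):
        return tuple(np.split(grad, splits, axis=axis))

    return Tensor._from_op(np.concatenate(datas, axis=axis), tuple(tensors), backward)
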