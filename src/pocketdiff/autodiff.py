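"""A minimal reverse-mode automatic-differentiation engine over numpy arrays.

Just enough machinery for the small reference denoiser: broadcast-aware
elementwise arithmetic, matmul, reductions, gather / scatter-add (for
message passing on graphs), and the nonlinearities the model uses. Not a
general tensor library — shapes are plain numpy shapes and everything runs
in float64 on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather", "scatter_add", "take_cols", "relu", "silu",
           "softmax", "sqrt", "absval", "log", "exp", "sigmoid", "tanh"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
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
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad: self._accum(g)
            if other.requires_grad: other._accum(g)
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad: self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad: self._accum(g * other.data)
            if other.requires_grad: other._accum(g * self.data)
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad: self._accum(g / other.data)
            if other.requires_grad: other._accum(-g * self.data / other.data**2)
        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))
        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad: self._accum(g @ other.data.T)
            if other.requires_grad: other._accum(self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = np.asarray(g)
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        def backward(g):
            if self.requires_grad: self._accum(np.asarray(g).reshape(old))
        return self._make(self.data.reshape(*shape), (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        def backward(g):
            pieces = np.split(np.asarray(g), np.cumsum(sizes)[:-1], axis=axis)
            for t, piece in zip(tensors, pieces):
                if t.requires_grad:
                    t._accum(piece)
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def gather(x: Tensor, indices: np.ndarray) -> Tensor:
    """Row gather: out[k] = x[indices[k]]."""
    indices = np.asarray(indices, dtype=int)
    def backward(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, indices, np.asarray(g))
            x._accum(acc)
    return x._make(x.data[indices], (x,), backward)


def take_cols(x: Tensor, n: int) -> Tensor:
    """First n columns of a 2-D tensor."""
    def backward(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            acc[:, :n] = np.asarray(g)
            x._accum(acc)
    return x._make(x.data[:, :n], (x,), backward)


def scatter_add(x: Tensor, indices: np.ndarray, n_out: int) -> Tensor:
    """Row scatter-add: out[i] = sum_{k: indices[k]=i} x[k]."""
    indices = np.asarray(indices, dtype=int)
    data = np.zeros((n_out,) + x.data.shape[1:])
    np.add.at(data, indices, x.data)
    def backward(g):
        if x.requires_grad:
            x._accum(np.asarray(g)[indices])
    return x._make(data, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    def backward(g):
        if x.requires_grad: x._accum(np.asarray(g) * mask)
    return x._make(x.data * mask, (x,), backward)


def silu(x: Tensor) -> Tensor:
    sig = 1.0 / (1.0 + np.exp(-x.data))
    def backward(g):
        if x.requires_grad:
            x._accum(np.asarray(g) * (sig + x.data * sig * (1 - sig)))
    return x._make(x.data * sig, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)
    def backward(g):
        if x.requires_grad: x._accum(np.asarray(g) * (1.0 - out_data**2))
    return x._make(out_data, (x,), backward)


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)
    def backward(g):
        if x.requires_grad: x._accum(np.asarray(g) * out_data)
    return x._make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))
    def backward(g):
        if x.requires_grad: x._accum(np.asarray(g) * out_data * (1.0 - out_data))
    return x._make(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad: x._accum(np.asarray(g) / x.data)
    return x._make(np.log(x.data), (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)
    def backward(g):
        if x.requires_grad: x._accum(np.asarray(g) * 0.5 / np.maximum(out_data, 1e-12))
    return x._make(out_data, (x,), backward)


def absval(x: Tensor, eps: float = 0.0) -> Tensor:
    """|x|; subgradient 0 at exactly 0 (eps smooths if nonzero)."""
    if eps > 0:
        return sqrt(x * x + Tensor(eps * eps)) - eps
    sign = np.sign(x.data)
    def backward(g):
        if x.requires_grad: x._accum(np.asarray(g) * sign)
    return x._make(np.abs(x.data), (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)
    def backward(g):
        if x.requires_grad:
            g = np.asarray(g)
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accum(out_data * (g - dot))
    return x._make(out_data, (x,), backward)
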