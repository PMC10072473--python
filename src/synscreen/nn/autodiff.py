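"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operation graph;
``backward()`` accumulates gradients by topological traversal. The
primitive set is exactly what the encoder families need: broadcasted
arithmetic, (batched) matmul, pointwise nonlinearities, softmax, axis
reductions including max, concatenation, reshape/transpose, and 1D/2D
window unfolding (im2col) from which convolutions are composed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "unfold1d", "unfold2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, inverting numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # --- graph machinery --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.requires_grad:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad += grad

    # --- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.expand_dims(g, -1) * b
                gb = np.tensordot(g, a, axes=(range(g.ndim), range(g.ndim)))
            elif a.ndim == 1:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                gb = np.expand_dims(a, -1) * np.expand_dims(g, -2)
            else:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    def square(self):
        return self * self

    # --- nonlinearities ----------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def leaky_relu(self, alpha: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, alpha * self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * np.where(self.data > 0, 1.0, alpha)
        )
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - val**2))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * val * (1.0 - val))
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        exp = np.exp(shifted)
        val = exp / exp.sum(axis=axis, keepdims=True)
        out = Tensor(val, _parents=(self,))

        def backward(g):
            inner = (g * val).sum(axis=axis, keepdims=True)
            self._accumulate(val * (g - inner))

        out._backward = backward
        return out

    # --- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def swap_last2(self):
        out = Tensor(np.swapaxes(self.data, -1, -2), _parents=(self,))
        out._backward = lambda g: self._accumulate(np.swapaxes(g, -1, -2))
        return out

    # --- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        val = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == val).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)  # ties share gradient
        out_val = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_val, _parents=(self,))

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask * g)

        out._backward = backward
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * g.ndim
            index[axis] = slice(lo, hi)
            t._accumulate(g[tuple(index)])

    out._backward = backward
    return out


def unfold1d(x: Tensor, kernel: int) -> Tensor:
    """im2col over the length axis: (B, L, C) -> (B, L-k+1, k*C)."""
    b, length, channels = x.shape
    l_out = length - kernel + 1
    if l_out < 1:
        raise ValueError(f"kernel {kernel} larger than sequence length {length}")
    windows = np.lib.stride_tricks.sliding_window_view(x.data, kernel, axis=1)
    # (B, L_out, C, k) -> (B, L_out, k, C) -> (B, L_out, k*C)
    val = windows.transpose(0, 1, 3, 2).reshape(b, l_out, kernel * channels)
    out = Tensor(val, _parents=(x,))

    def backward(g):
        g = g.reshape(b, l_out, kernel, channels)
        gx = np.zeros_like(x.data)
        for i in range(kernel):
            gx[:, i : i + l_out, :] += g[:, :, i, :]
        x._accumulate(gx)

    out._backward = backward
    return out


def unfold2d(x: Tensor, kh: int, kw: int) -> Tensor:
    """im2col over height/width: (B, H, W, C) -> (B, Ho, Wo, kh*kw*C)."""
    b, h, w, c = x.shape
    ho, wo = h - kh + 1, w - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"kernel ({kh},{kw}) larger than image ({h},{w})")
    windows = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(1, 2))
    # (B, Ho, Wo, C, kh, kw) -> (B, Ho, Wo, kh, kw, C)
    val = windows.transpose(0, 1, 2, 4, 5, 3).reshape(b, ho, wo, kh * kw * c)
    out = Tensor(val, _parents=(x,))

    def backward(g):
        g = g.reshape(b, ho, wo, kh, kw, c)
        gx = np.zeros_like(x.data)
        for i in range(kh):
            for j in range(kw):
                gx[:, i : i + ho, j : j + wo, :] += g[:, :, :, i, j, :]
        x._accumulate(gx)

    out._backward = backward
    return out
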