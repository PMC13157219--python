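"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the completion networks need: broadcasted
arithmetic, matmul, elementwise nonlinearities, single-axis reductions
(sum / mean / max / min with argmax-style gradient routing), reshape,
concatenation, fancy indexing, repeat, and a 2-D convolution primitive.
Everything is float64; graphs are built eagerly and freed after
``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev if self.requires_grad else ()
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            node._backward = None
            node._prev = ()

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._coerce(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out = Tensor(self.data**exponent, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                gx = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(gx, self.shape))
            if other.requires_grad:
                gw = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gw, other.shape))

        out._backward = bwd
        return out

    # ----------------------------------------------------------- nonlinearity
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        mask = self.data > 0
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1.0 - y**2))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y * (1.0 - y))
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def sqrt(self):
        return self.pow(0.5)

    def clip_min(self, lo: float):
        out = Tensor(np.maximum(self.data, lo), _prev=(self,))
        mask = self.data > lo
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def _extremum(self, axis: int, argfn):
        idx = argfn(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out = Tensor(np.squeeze(val, axis=axis), _prev=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis)
            self._accum(full)

        out._backward = bwd
        return out

    def amax(self, axis: int):
        """Max along one axis; gradient routed to the (first) argmax."""
        return self._extremum(axis, np.argmax)

    def amin(self, axis: int):
        """Min along one axis; gradient routed to the (first) argmin."""
        return self._extremum(axis, np.argmin)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.shape))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(np.swapaxes(g, a, b))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    def repeat(self, repeats: int, axis: int):
        """np.repeat along one axis (each element duplicated consecutively)."""
        out = Tensor(np.repeat(self.data, repeats, axis=axis), _prev=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            shp = list(self.shape)
            shp[axis:axis + 1] = [self.shape[axis], repeats]
            self._accum(g.reshape(shp).sum(axis=axis + 1))

        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(gpart)

    out._backward = bwd
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*kh*kw, Hout*Wout) patch matrix."""
    b, c, h, w = x.shape
    hout = (h - kh) // stride + 1
    wout = (w - kw) // stride + 1
    cols = np.empty((b, c, kh, kw, hout, wout), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * hout:stride, j:j + stride * wout:stride]
    return cols.reshape(b, c * kh * kw, hout * wout)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    b, c, h, w = x_shape
    hout = (h - kh) // stride + 1
    wout = (w - kw) // stride + 1
    cols = cols.reshape(b, c, kh, kw, hout, wout)
    x = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i:i + stride * hout:stride, j:j + stride * wout:stride] += cols[:, :, i, j]
    return x


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """2-D convolution (cross-correlation): x (B,C,H,W), weight (O,C,kh,kw)."""
    o, c, kh, kw = weight.shape
    b, _, h, w = x.shape
    hout = (h - kh) // stride + 1
    wout = (w - kw) // stride + 1
    cols = _im2col(x.data, kh, kw, stride)  # (B, C*kh*kw, L)
    wmat = weight.data.reshape(o, -1)
    out_data = (wmat @ cols).reshape(b, o, hout, wout) + bias.data.reshape(1, o, 1, 1)
    out = Tensor(out_data, _prev=(x, weight, bias))

    def bwd(g):
        gmat = g.reshape(b, o, -1)  # (B, O, L)
        if weight.requires_grad:
            gw = np.einsum("bol,bkl->ok", gmat, cols).reshape(weight.shape)
            weight._accum(gw)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("ok,bol->bkl", wmat, gmat)
            x._accum(_col2im(gcols, x.shape, kh, kw, stride))

    out._backward = bwd
    return out
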