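"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the scaled-down segmentation and
classification networks need: broadcast elementwise arithmetic, matmul,
2D/3D convolution (via im2col), max pooling, nearest-neighbour upsampling,
channel concatenation, relu/sigmoid/log/pow and reductions. Gradients flow
through a taped graph released after each backward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "sigmoid", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    DTYPE = np.float32  # single precision: the nets are small and bandwidth-bound

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None):
        self.data = np.asarray(data, dtype=self.DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- graph plumbing -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            t._parents = ()  # release the tape

    # -- elementwise --------------------------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(bwd_self(g), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(bwd_other(g), other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    def __add__(self, other):
        return self._binary(other, np.add, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        return self._binary(o, np.multiply,
                            lambda g: g * o.data, lambda g: g * self.data)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        return self * o.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out_data = np.power(self.data, exponent)

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * np.power(self.data, exponent - 1.0))

        return Tensor(out_data, parents=(self,), backward=backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor(s, parents=(self,), backward=backward)

    # -- reductions / reshaping --------------------------------------------
    def sum(self):
        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(self.data.sum(), parents=(self,), backward=backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, self.data.shape))

        return Tensor(self.data.mean(), parents=(self,), backward=backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,),
                      backward=backward)

    # -- linear algebra -----------------------------------------------------
    def matmul(self, other: "Tensor"):
        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other),
                      backward=backward)

    # -- convolution --------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor"):
        """Same-padded 2D convolution; x (N,C,H,W), w (O,C,kh,kw)."""
        x = self.data
        w = weight.data
        n, c, h, wd = x.shape
        o, _, kh, kw = w.shape
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
        cols2 = cols.reshape(n * h * wd, c * kh * kw)
        wmat = w.reshape(o, -1)
        out = cols2 @ wmat.T + bias.data
        out = out.reshape(n, h, wd, o).transpose(0, 3, 1, 2)

        def backward(g):
            gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
            if weight.requires_grad:
                weight._accum((gmat.T @ cols2).reshape(w.shape))
            if bias.requires_grad:
                bias._accum(gmat.sum(axis=0))
            if self.requires_grad:
                dcols = (gmat @ wmat).reshape(n, h, wd, c, kh, kw)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + h, j:j + wd] += dcols[
                            :, :, :, :, i, j].transpose(0, 3, 1, 2)
                self._accum(dxp[:, :, ph:ph + h, pw:pw + wd])

        return Tensor(out, parents=(self, weight, bias), backward=backward)

    def conv3d(self, weight: "Tensor", bias: "Tensor"):
        """Same-padded 3D convolution; x (N,C,D1,D2,D3), w (O,C,k1,k2,k3)."""
        x = self.data
        w = weight.data
        n, c, d1, d2, d3 = x.shape
        o, _, k1, k2, k3 = w.shape
        p1, p2, p3 = k1 // 2, k2 // 2, k3 // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p1, p1), (p2, p2), (p3, p3)))
        cols = sliding_window_view(xp, (k1, k2, k3), axis=(2, 3, 4))
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols2 = cols.reshape(n * d1 * d2 * d3, c * k1 * k2 * k3)
        wmat = w.reshape(o, -1)
        out = cols2 @ wmat.T + bias.data
        out = out.reshape(n, d1, d2, d3, o).transpose(0, 4, 1, 2, 3)

        def backward(g):
            gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, o)
            if weight.requires_grad:
                weight._accum((gmat.T @ cols2).reshape(w.shape))
            if bias.requires_grad:
                bias._accum(gmat.sum(axis=0))
            if self.requires_grad:
                dcols = (gmat @ wmat).reshape(n, d1, d2, d3, c, k1, k2, k3)
                dxp = np.zeros_like(xp)
                for i in range(k1):
                    for j in range(k2):
                        for k in range(k3):
                            dxp[:, :, i:i + d1, j:j + d2, k:k + d3] += dcols[
                                :, :, :, :, :, i, j, k].transpose(0, 4, 1, 2, 3)
                self._accum(dxp[:, :, p1:p1 + d1, p2:p2 + d2, p3:p3 + d3])

        return Tensor(out, parents=(self, weight, bias), backward=backward)

    # -- pooling / upsampling ----------------------------------------------
    def maxpool2d(self):
        """2x2 max pooling (dims must be even)."""
        n, c, h, w = self.data.shape
        xr = self.data.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]

        def backward(g):
            if self.requires_grad:
                gg = g[:, :, :, None, :, None] * mask
                self._accum(gg.reshape(n, c, h, w))

        return Tensor(out, parents=(self,), backward=backward)

    def maxpool3d(self, kernel=(2, 2, 2)):
        n, c, d1, d2, d3 = self.data.shape
        a, b, cc = kernel
        xr = self.data.reshape(n, c, d1 // a, a, d2 // b, b, d3 // cc, cc)
        out = xr.max(axis=(3, 5, 7))
        mask = xr == out[:, :, :, None, :, None, :, None]

        def backward(g):
            if self.requires_grad:
                gg = g[:, :, :, None, :, None, :, None] * mask
                self._accum(gg.reshape(n, c, d1, d2, d3))

        return Tensor(out, parents=(self,), backward=backward)

    def upsample2d(self):
        """Nearest-neighbour 2x upsampling."""
        def backward(g):
            if self.requires_grad:
                n, c, h2, w2 = g.shape
                gr = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2)
                self._accum(gr.sum(axis=(3, 5)))

        out = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)
        return Tensor(out, parents=(self,), backward=backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def backward(g):
        splits = np.cumsum(sizes)[:-1]
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(gpart)

    return Tensor(out, parents=tuple(tensors), backward=backward)


def sigmoid(t: Tensor) -> Tensor:
    return t.sigmoid()


def relu(t: Tensor) -> Tensor:
    return t.relu()
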