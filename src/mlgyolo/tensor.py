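"""Reverse-mode automatic differentiation on numpy arrays.

A small tensor core sufficient for training convolutional detectors on the
CPU: NCHW convolutions (grouped/depthwise) via im2col, batch norm, pooling,
nearest-neighbour upsampling, and the pointwise/reduction ops needed by
transformer layers and IoU-based losses. Float32 throughout.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad"]


class _NoGrad:
    _depth = 0

    def __enter__(self):
        _NoGrad._depth += 1
        return self

    def __exit__(self, *exc):
        _NoGrad._depth -= 1
        return False

    @staticmethod
    def active() -> bool:
        return _NoGrad._depth > 0


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and not _NoGrad.active()
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if not _NoGrad.active() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        g = g.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._prev))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen and child.requires_grad:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closure memory

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._coerce(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)

        return Tensor._make(out_data, tensors, backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise --------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = _stable_sigmoid(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def silu(self):
        s = _stable_sigmoid(self.data)
        out_data = self.data * s

        def backward(g):
            if self.requires_grad:
                self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return self._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), backward)

    def atan(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / (1.0 + self.data ** 2))

        return self._make(np.arctan(self.data), (self,), backward)

    def maximum(self, other):
        other = self._coerce(other)
        out_data = np.maximum(self.data, other.data)

        def backward(g):
            mask = self.data >= other.data
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * (~mask), other.shape))

        return self._make(out_data, (self, other), backward)

    def minimum(self, other):
        other = self._coerce(other)
        out_data = np.minimum(self.data, other.data)

        def backward(g):
            mask = self.data <= other.data
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * (~mask), other.shape))

        return self._make(out_data, (self, other), backward)

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * ((self.data >= lo) & (self.data <= hi)))

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- spatial ops (NCHW) ----------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, dilation: int = 1,
               groups: int = 1) -> "Tensor":
        """2-D cross-correlation. weight: (Cout, Cin/groups, kh, kw)."""
        x, w = self, weight
        n, cin, h, wdt = x.shape
        cout, cin_g, kh, kw = w.shape
        assert cin == cin_g * groups, "channel/group mismatch"
        ho = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
        wo = (wdt + 2 * padding - dilation * (kw - 1) - 1) // stride + 1

        cols = _im2col(x.data, kh, kw, stride, padding, dilation)  # (n, cin*kh*kw, ho*wo)
        cols_g = cols.reshape(n, groups, cin_g * kh * kw, ho * wo)
        wm = w.data.reshape(groups, cout // groups, cin_g * kh * kw)
        out = np.einsum("gok,ngkp->ngop", wm, cols_g, optimize=True)
        out_data = out.reshape(n, cout, ho, wo)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, cout, 1, 1)

        parents = (x, w) if bias is None else (x, w, bias)

        def backward(g):
            gm = g.reshape(n, groups, cout // groups, ho * wo)
            if w.requires_grad:
                gw = np.einsum("ngop,ngkp->gok", gm, cols_g, optimize=True)
                w._accum(gw.reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gcols = np.einsum("gok,ngop->ngkp", wm, gm, optimize=True)
                gcols = gcols.reshape(n, cin * kh * kw, ho * wo)
                gx = _col2im(gcols, x.shape, kh, kw, stride, padding, dilation)
                x._accum(gx)

        return self._make(out_data, parents, backward)

    def maxpool2d(self, k: int, stride: int | None = None, padding: int = 0):
        stride = stride or k
        x = self
        n, c, h, w = x.shape
        ho = (h + 2 * padding - k) // stride + 1
        wo = (w + 2 * padding - k) // stride + 1
        cols = _im2col(x.data.reshape(n * c, 1, h, w), k, k, stride, padding, 1,
                       pad_value=-np.inf)
        cols = cols.reshape(n * c, k * k, ho * wo)
        arg = cols.argmax(axis=1)
        out_data = np.take_along_axis(cols, arg[:, None, :], axis=1)[:, 0, :]
        out_data = out_data.reshape(n, c, ho, wo)

        def backward(g):
            if not x.requires_grad:
                return
            gcols = np.zeros((n * c, k * k, ho * wo), dtype=np.float32)
            np.put_along_axis(gcols, arg[:, None, :], g.reshape(n * c, 1, ho * wo), axis=1)
            gx = _col2im(gcols, (n * c, 1, h, w), k, k, stride, padding, 1)
            x._accum(gx.reshape(x.shape))

        return self._make(out_data, (x,), backward)

    def upsample_nearest(self, factor: int = 2):
        x = self
        out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

        def backward(g):
            if not x.requires_grad:
                return
            n, c, h, w = x.shape
            gx = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            x._accum(gx)

        return self._make(out_data, (x,), backward)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    """1/(1+exp(-x)) without overflow for large |x| in float32."""
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int,
            dilation: int, pad_value: float = 0.0) -> np.ndarray:
    """(n, c, h, w) -> (n, c*kh*kw, ho*wo) patch matrix."""
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                   constant_values=pad_value)
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - dilation * (kh - 1) - 1) // stride + 1
    wo = (wp - dilation * (kw - 1) - 1) // stride + 1
    s = x.strides
    shape = (n, c, kh, kw, ho, wo)
    strides = (s[0], s[1], s[2] * dilation, s[3] * dilation, s[2] * stride, s[3] * stride)
    patches = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    return np.ascontiguousarray(patches).reshape(n, c * kh * kw, ho * wo)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int,
            padding: int, dilation: int) -> np.ndarray:
    """Adjoint of _im2col (scatter-add patches back)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    ho = (hp - dilation * (kh - 1) - 1) // stride + 1
    wo = (wp - dilation * (kw - 1) - 1) // stride + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=np.float32)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            out[:, :, hi:hi + stride * ho:stride, wj:wj + stride * wo:stride] += cols[:, :, i, j]
    if padding:
        out = out[:, :, padding:padding + h, padding:padding + w]
    return out
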