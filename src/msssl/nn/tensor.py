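"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the micrograd style, extended with the array
operations a convolutional/transformer model needs: broadcasting arithmetic,
batched matmul, reductions, shape surgery, 2-D convolution and transposed
convolution (im2col/col2im), max pooling, nearest and bilinear resampling.
All data is float32. Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` after a topological sort of the tape.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _f32(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _f32(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _op(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- introspection --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._op(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return Tensor._op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p
        x = self.data

        def backward(g):
            return (g * p * x ** (p - 1.0),)

        return Tensor._op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def backward(g):
            ga = _unbroadcast(g @ b.swapaxes(-1, -2), a.shape)
            gb = _unbroadcast(a.swapaxes(-1, -2) @ g, b.shape)
            return (ga, gb)

        return Tensor._op(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._op(out_data, (self,), backward)

    def log(self):
        x = self.data

        def backward(g):
            return (g / x,)

        return Tensor._op(np.log(x), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._op(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data * out_data),)

        return Tensor._op(out_data, (self,), backward)

    def gelu(self):
        # exact GELU: x * Phi(x), with the erf-based normal CDF
        x = self.data.astype(np.float64)
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        out_data = (x * cdf).astype(np.float32)
        dydx = (cdf + x * pdf).astype(np.float32)

        def backward(g):
            return (g * dydx,)

        return Tensor._op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(np.asarray(g, np.float32), shape).copy(),)
            gg = g
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % len(shape) for a in ax)
                for a in sorted(ax):
                    gg = np.expand_dims(gg, a)
            return (np.broadcast_to(gg, shape).astype(np.float32, copy=True),)

        return Tensor._op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == expanded)
        count = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            return ((mask / count * gg).astype(np.float32),)

        return Tensor._op(out_data, (self,), backward)

    # -- shape surgery ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            return (g.reshape(old),)

        return Tensor._op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._op(np.ascontiguousarray(self.data.transpose(axes)), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape

        def backward(g):
            dx = np.zeros(shape, np.float32)
            np.add.at(dx, idx, g)
            return (dx,)

        return Tensor._op(np.ascontiguousarray(out_data), (self,), backward)

    # -- backward pass ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited = set()
        stack = [(self, False)]
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
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = _f32(grad)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._prev, grads):
                if g is None or not (parent.requires_grad or parent._prev):
                    continue
                if parent.grad is None:
                    parent.grad = _f32(g)
                else:
                    parent.grad = parent.grad + _f32(g)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def cat(tensors, axis=0):
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.ascontiguousarray(np.take(g, range(offsets[i], offsets[i + 1]), axis=axis))
            for i in range(len(sizes))
        )

    return Tensor._op(out_data, tuple(tensors), backward)


def stack(tensors, axis=0):
    expanded = [t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors]
    return cat(expanded, axis=axis)


def softmax(x: Tensor, axis=-1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # stop-gradient shift
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis=-1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


# ---------------------------------------------------------------------------
# im2col / col2im convolution machinery
# ---------------------------------------------------------------------------

def _pad_hw(pad):
    return (pad, pad) if isinstance(pad, int) else tuple(pad)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad):
    n, c, h, w = x.shape
    ph, pw = _pad_hw(pad)
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if ph or pw else x
    hp, wp = xp.shape[2], xp.shape[3]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, oh, ow, kh, kw), (s0, s1, s2 * stride, s3 * stride, s2, s3)
    )
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * oh * ow, c * kh * kw)
    return cols, oh, ow


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad):
    n, c, h, w = xshape
    ph, pw = _pad_hw(pad)
    hp, wp = h + 2 * ph, w + 2 * pw
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    dxp = np.zeros((n, c, hp, wp), np.float32)
    d = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d[:, :, :, :, i, j]
    return dxp[:, :, ph:ph + h, pw:pw + w] if (ph or pw) else dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1, pad=0) -> Tensor:
    """2-D cross-correlation; weight (Cout, Cin, kh, kw)."""
    n, cin, h, w = x.shape
    cout, _, kh, kw = weight.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(cout, -1)
    out = cols @ wmat.T
    if bias is not None:
        out = out + bias.data
    out_data = out.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        dw = (gmat.T @ cols).reshape(weight.shape)
        dcols = gmat @ wmat
        dx = _col2im(dcols, x.shape, kh, kw, stride, pad)
        if bias is None:
            return (dx, dw)
        return (dx, dw, gmat.sum(axis=0))

    return Tensor._op(np.ascontiguousarray(out_data), parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 2, pad: int = 1, output_pad: int = 1) -> Tensor:
    """Fractionally-strided 2-D convolution; weight (Cin, Cout, kh, kw)."""
    n, cin, h, w = x.shape
    _, cout, kh, kw = weight.shape
    out_h = (h - 1) * stride - 2 * pad + kh + output_pad
    out_w = (w - 1) * stride - 2 * pad + kw + output_pad
    buf_h = (h - 1) * stride + kh + output_pad
    buf_w = (w - 1) * stride + kw + output_pad
    xmat = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(n * h * w, cin)
    wmat = weight.data.reshape(cin, cout * kh * kw)
    t = (xmat @ wmat).reshape(n, h, w, cout, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    buf = np.zeros((n, cout, buf_h, buf_w), np.float32)
    for a in range(kh):
        for b in range(kw):
            buf[:, :, a:a + stride * h:stride, b:b + stride * w:stride] += t[:, :, :, :, a, b]
    out_data = buf[:, :, pad:pad + out_h, pad:pad + out_w]
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        dbuf = np.zeros((n, cout, buf_h, buf_w), np.float32)
        dbuf[:, :, pad:pad + out_h, pad:pad + out_w] = g
        s0, s1, s2, s3 = dbuf.strides
        win = np.lib.stride_tricks.as_strided(
            dbuf, (n, cout, h, w, kh, kw), (s0, s1, s2 * stride, s3 * stride, s2, s3)
        )
        winmat = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, cout * kh * kw)
        dx = (winmat @ wmat.T).reshape(n, h, w, cin).transpose(0, 3, 1, 2)
        dw = (xmat.T @ winmat).reshape(weight.shape)
        if bias is None:
            return (np.ascontiguousarray(dx), dw)
        return (np.ascontiguousarray(dx), dw, g.sum(axis=(0, 2, 3)))

    return Tensor._op(np.ascontiguousarray(out_data), parents, backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    n, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf) if pad else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    oh = (hp - kernel) // stride + 1
    ow = (wp - kernel) // stride + 1
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, oh, ow, kernel, kernel), (s0, s1, s2 * stride, s3 * stride, s2, s3)
    ).reshape(n, c, oh, ow, kernel * kernel)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxp = np.zeros((n, c, hp, wp), np.float32)
        ni, ci, oi, oj = np.indices((n, c, oh, ow))
        ri = oi * stride + idx // kernel
        rj = oj * stride + idx % kernel
        np.add.at(dxp, (ni, ci, ri, rj), g)
        return (dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp,)

    return Tensor._op(np.ascontiguousarray(out_data), (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return Tensor._op(out_data, (x,), backward)


def _bilinear_coeffs(in_size: int, out_size: int):
    # align_corners=False sampling grid
    scale = in_size / out_size
    src = (np.arange(out_size, dtype=np.float64) + 0.5) * scale - 0.5
    src = np.clip(src, 0.0, in_size - 1.0)
    i0 = np.floor(src).astype(np.int64)
    i1 = np.minimum(i0 + 1, in_size - 1)
    frac = (src - i0).astype(np.float32)
    return i0, i1, frac


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    n, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x * 1.0
    i0, i1, fi = _bilinear_coeffs(h, out_h)
    j0, j1, fj = _bilinear_coeffs(w, out_w)
    wi = fi[None, None, :, None]
    wj = fj[None, None, None, :]
    d = x.data
    top = (1 - wj) * d[:, :, i0][:, :, :, j0] + wj * d[:, :, i0][:, :, :, j1]
    bot = (1 - wj) * d[:, :, i1][:, :, :, j0] + wj * d[:, :, i1][:, :, :, j1]
    out_data = (1 - wi) * top + wi * bot

    def backward(g):
        dx = np.zeros((n, c, h, w), np.float32)
        for ii, wwi in ((i0, (1 - fi)), (i1, fi)):
            for jj, wwj in ((j0, (1 - fj)), (j1, fj)):
                gg = g * wwi[None, None, :, None] * wwj[None, None, None, :]
                np.add.at(dx, (slice(None), slice(None), ii[:, None], jj[None, :]), gg)
        return (dx,)

    return Tensor._op(out_data.astype(np.float32), (x,), backward)
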