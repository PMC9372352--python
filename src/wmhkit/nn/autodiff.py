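"""Reverse-mode automatic differentiation over NumPy arrays.

A minimal tape-based engine sufficient for a 2D fully convolutional
encoder--decoder: broadcasting arithmetic, reductions, exp/log/relu, and
fused layer ops (im2col GEMM convolutions, batch normalization, PReLU,
channel softmax) with hand-written backward passes. All gradients are
checked against finite differences in the test suite.

`DEFAULT_DTYPE` (float32) sets the precision of newly created tensors;
tests that do finite-difference checks switch it to float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv3x3", "conv1x1", "down2x2", "up2x2", "relu",
           "prelu", "batchnorm", "softmax_channels", "DEFAULT_DTYPE"]

DEFAULT_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
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
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype != DEFAULT_DTYPE and not parents:
            data = data.astype(DEFAULT_DTYPE)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
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
            for p in node._parents:
                stack.append((p, False))
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))
        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))
        out._backward = bwd
        return out

    # -- reductions & elementwise -----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bwd
        return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * mask)
    out._backward = bwd
    return out


def prelu(x: Tensor, a: Tensor) -> Tensor:
    """Per-channel parametric ReLU on (N, C, H, W); a has shape (C,)."""
    av = a.data[None, :, None, None]
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, av * x.data), parents=(x, a))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * np.where(pos, 1.0, av))
        if a.requires_grad:
            a._accum((g * np.where(pos, 0.0, x.data)).sum(axis=(0, 2, 3)))
    out._backward = bwd
    return out


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) zero-padded by 1 -> contiguous (N*H*W, C*9) patch matrix."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * 9)


def conv3x3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same' 2D convolution, stride 1, zero padding 1.

    x: (N, Cin, H, W); w: (Cout, Cin, 3, 3); b: (Cout,).
    """
    n, c, h, wd = x.data.shape
    o = w.data.shape[0]
    cols = _im2col(x.data)
    wmat = w.data.reshape(o, c * 9)
    y = (cols @ wmat.T).reshape(n, h, wd, o).transpose(0, 3, 1, 2) + \
        b.data[None, :, None, None]
    out = Tensor(y, parents=(x, w, b))

    def bwd(g):
        g2d = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * wd, o)
        if w.requires_grad:
            w._accum((g2d.T @ cols).reshape(o, c, 3, 3))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # grad wrt input = 'same' correlation of g with the flipped kernel
            gcols = _im2col(g)
            wflip = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)).reshape(c, o * 9)
            x._accum((gcols @ wflip.T).reshape(n, h, wd, c).transpose(0, 3, 1, 2))
    out._backward = bwd
    return out


def conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Pointwise convolution. w: (Cout, Cin)."""
    n, c, h, wd = x.data.shape
    o = w.data.shape[0]
    xm = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(-1, c)
    y = (xm @ w.data.T).reshape(n, h, wd, o).transpose(0, 3, 1, 2) + \
        b.data[None, :, None, None]
    out = Tensor(y, parents=(x, w, b))

    def bwd(g):
        g2d = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
        if w.requires_grad:
            w._accum(g2d.T @ xm)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum((g2d @ w.data).reshape(n, h, wd, c).transpose(0, 3, 1, 2))
    out._backward = bwd
    return out


def down2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 convolution with stride 2 (non-overlapping). w: (Cout, Cin, 2, 2)."""
    n, c, h, wd = x.data.shape
    if h % 2 or wd % 2:
        raise ValueError("down2x2 requires even spatial dimensions")
    o = w.data.shape[0]
    h2, w2 = h // 2, wd // 2
    xm = np.ascontiguousarray(
        x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 2, 4, 1, 3, 5)
    ).reshape(n * h2 * w2, c * 4)
    wmat = w.data.reshape(o, c * 4)
    y = (xm @ wmat.T).reshape(n, h2, w2, o).transpose(0, 3, 1, 2) + \
        b.data[None, :, None, None]
    out = Tensor(y, parents=(x, w, b))

    def bwd(g):
        g2d = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
        if w.requires_grad:
            w._accum((g2d.T @ xm).reshape(o, c, 2, 2))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = (g2d @ wmat).reshape(n, h2, w2, c, 2, 2)
            x._accum(gx.transpose(0, 3, 1, 4, 2, 5).reshape(n, c, h, wd))
    out._backward = bwd
    return out


def up2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 transposed convolution with stride 2. w: (Cin, Cout, 2, 2)."""
    n, c, h, wd = x.data.shape
    o = w.data.shape[1]
    xm = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(-1, c)
    wmat = w.data.reshape(c, o * 4)
    y = (xm @ wmat).reshape(n, h, wd, o, 2, 2).transpose(0, 3, 1, 4, 2, 5)
    y = y.reshape(n, o, 2 * h, 2 * wd) + b.data[None, :, None, None]
    out = Tensor(y, parents=(x, w, b))

    def bwd(g):
        gr = np.ascontiguousarray(
            g.reshape(n, o, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        ).reshape(n * h * wd, o * 4)
        if w.requires_grad:
            w._accum((xm.T @ gr).reshape(c, o, 2, 2))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum((gr @ wmat.T).reshape(n, h, wd, c).transpose(0, 3, 1, 2))
    out._backward = bwd
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Batch normalization over (N, H, W) per channel, training mode.

    Returns (out, batch_mean, batch_var) -- the batch statistics let the
    caller maintain running averages for inference.
    """
    axes = (0, 2, 3)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    var = np.square(x.data - mu).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = (x.data - mu) * inv
    gv = gamma.data[None, :, None, None]
    out = Tensor(xn * gv + beta.data[None, :, None, None],
                 parents=(x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xn).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gsum = g.sum(axis=axes, keepdims=True)
            gxn = (g * xn).sum(axis=axes, keepdims=True)
            x._accum(gv * inv / m * (m * g - gsum - xn * gxn))
    out._backward = bwd
    return out, mu.ravel(), var.ravel()


def softmax_channels(x: Tensor) -> Tensor:
    """Numerically stable softmax over the channel axis of (N, C, H, W)."""
    m = x.data.max(axis=1, keepdims=True)
    e = np.exp(x.data - m)
    p = e / e.sum(axis=1, keepdims=True)
    out = Tensor(p, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            dot = (g * p).sum(axis=1, keepdims=True)
            x._accum(p * (g - dot))
    out._backward = bwd
    return out
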