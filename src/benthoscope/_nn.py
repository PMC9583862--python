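"""Minimal reverse-mode autograd on numpy for small convolutional nets.

No deep-learning framework ships with this environment, and the translation
networks here are small enough (64-pixel tiles, tens of channels) that
im2col convolutions in float32 numpy train in minutes on one CPU.  This
module provides exactly the operations the pix2pix networks need: strided
convolution and transposed convolution (kernel 4, stride 2 in practice),
train-mode batch normalization, leaky ReLU / ReLU / tanh, channel
concatenation, L1 and binary-cross-entropy-with-logits losses, and Adam.

Gradients are validated against central finite differences in the test
suite; everything is deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "conv2d", "conv_transpose2d", "batchnorm", "leaky_relu", "relu",
    "tanh", "concat", "l1_loss", "bce_with_logits", "add", "scale", "Adam",
    "Conv2d", "ConvTranspose2d", "BatchNorm2d",
]


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out._prev = tuple(p for p in parents if isinstance(p, Tensor))
    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution primitives (pure numpy, NCHW)


def _im2col(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    # xp (N,C,Hp,Wp) -> (N, Ho, Wo, C*k*k)
    v = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    n, c, ho, wo = v.shape[:4]
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho, wo, c * k * k)


def _conv_fwd(x, w, s, p):
    n, c, h, wd = x.shape
    co, ci, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = _im2col(xp, k, s)
    y = cols @ w.reshape(co, -1).T
    return y.transpose(0, 3, 1, 2), cols


def _conv_dw(cols, dout, wshape):
    co = wshape[0]
    d2 = dout.transpose(0, 2, 3, 1).reshape(-1, co)
    return (d2.T @ cols.reshape(-1, cols.shape[-1])).reshape(wshape)


def _conv_dx(dout, w, s, p, out_hw):
    # adjoint of _conv_fwd; also the forward pass of transposed convolution
    n, co, ho, wo = dout.shape
    _, ci, k, _ = w.shape
    h, wd = out_hw
    d2 = dout.transpose(0, 2, 3, 1).reshape(-1, co)
    dcols = (d2 @ w.reshape(co, -1)).reshape(n, ho, wo, ci, k, k).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, ci, h + 2 * p, wd + 2 * p), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + (ho - 1) * s + 1:s, j:j + (wo - 1) * s + 1:s] += dcols[..., i, j]
    return dxp[:, :, p:p + h, p:p + wd]


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2, pad: int = 1) -> Tensor:
    """y = conv(x, w) + b; x (N,Cin,H,W), w (Cout,Cin,k,k), b (Cout,)."""
    y, cols = _conv_fwd(x.data, w.data, stride, pad)
    y = y + b.data[None, :, None, None]
    hw = x.data.shape[2:]

    def backward(g):
        w._accum(_conv_dw(cols, g, w.data.shape))
        b._accum(g.sum(axis=(0, 2, 3)))
        x._accum(_conv_dx(g, w.data, stride, pad, hw))

    return _node(y, (x, w, b), backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2, pad: int = 1) -> Tensor:
    """Transposed convolution; x (N,Cin,H,W), w (Cin,Cout,k,k), b (Cout,).

    Output spatial size (H-1)*stride - 2*pad + k — exact 2x upsampling for
    kernel 4, stride 2, pad 1.
    """
    n, ci, h, wd = x.shape
    k = w.data.shape[2]
    out_hw = ((h - 1) * stride - 2 * pad + k, (wd - 1) * stride - 2 * pad + k)
    y = _conv_dx(x.data, w.data, stride, pad, out_hw) + b.data[None, :, None, None]

    def backward(g):
        # dL/dx = conv(g, w); dL/dw accumulates through the same im2col of g
        gp = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = _im2col(gp, k, stride)
        x._accum((cols @ w.data.reshape(ci, -1).T).transpose(0, 3, 1, 2))
        w._accum(_conv_dw(cols, x.data, w.data.shape))
        b._accum(g.sum(axis=(0, 2, 3)))

    return _node(y, (x, w, b), backward)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W), train-mode statistics."""
    ax = (0, 2, 3)
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        gamma._accum((g * xhat).sum(axis=ax))
        beta._accum(g.sum(axis=ax))
        dxhat = g * gamma.data[None, :, None, None]
        x._accum(inv / m * (
            m * dxhat
            - dxhat.sum(axis=ax, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=ax, keepdims=True)
        ))

    return _node(y, (x, gamma, beta), backward)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0
    y = np.where(mask, x.data, slope * x.data)

    def backward(g):
        x._accum(np.where(mask, g, np.float32(slope) * g))

    return _node(y, (x,), backward)


def relu(x: Tensor) -> Tensor:
    return leaky_relu(x, 0.0)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)

    def backward(g):
        x._accum(g * (1.0 - y * y))

    return _node(y, (x,), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis (skip connections)."""
    ca = a.data.shape[1]
    y = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        a._accum(g[:, :ca])
        b._accum(g[:, ca:])

    return _node(y, (a, b), backward)


def l1_loss(a: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute error against a constant target."""
    diff = a.data - target
    y = np.abs(diff).mean()

    def backward(g):
        a._accum(g * np.sign(diff) / diff.size)

    return _node(y, (a,), backward)


def bce_with_logits(x: Tensor, target: float) -> Tensor:
    """Mean binary cross-entropy of logits against a constant label."""
    z = x.data
    y = (np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))).mean()

    def backward(g):
        sig = 1.0 / (1.0 + np.exp(-z))
        x._accum(g * (sig - target) / z.size)

    return _node(y, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accum(g)
        b._accum(g)

    return _node(a.data + b.data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        a._accum(g * np.float32(s))

    return _node(a.data * np.float32(s), (a,), backward)


# ---------------------------------------------------------------------------
# layers and optimizer


class Conv2d:
    def __init__(self, cin, cout, rng, k=4, stride=2, pad=1):
        self.w = Tensor(rng.normal(0.0, 0.02, (cout, cin, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return conv2d(x, self.w, self.b, self.stride, self.pad)

    def params(self):
        return [self.w, self.b]


class ConvTranspose2d:
    def __init__(self, cin, cout, rng, k=4, stride=2, pad=1):
        self.w = Tensor(rng.normal(0.0, 0.02, (cin, cout, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return conv_transpose2d(x, self.w, self.b, self.stride, self.pad)

    def params(self):
        return [self.w, self.b]


class BatchNorm2d:
    def __init__(self, c, rng):
        self.gamma = Tensor(rng.normal(1.0, 0.02, c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)

    def __call__(self, x):
        return batchnorm(x, self.gamma, self.beta)

    def params(self):
        return [self.gamma, self.beta]


class Adam:
    """Adam with pix2pix's customary beta1 = 0.5."""

    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
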