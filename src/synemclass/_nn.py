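"""Minimal CPU convolutional-network framework (numpy, manual backprop).

Just enough machinery for the patch classifiers in this package: strided
convolution via sliding windows + einsum, ReLU, global average pooling and
a bias-free linear head, trained with momentum SGD on softmax
cross-entropy.  Bias-free heads matter downstream: the class-activation
identity (spatial mean of the weight-projected feature map == logit) only
holds without a bias term.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "Linear", "Sequential", "SGD",
           "softmax", "cross_entropy_grad", "global_avg_pool"]


class Conv2d:
    def __init__(self, c_in, c_out, k, stride=1, pad=0, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in),
                            (c_out, c_in, k, k)).astype(np.float64)
        self.b = np.zeros(c_out) if bias else None
        self.k, self.stride, self.pad = k, stride, pad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._xp = None

    @property
    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    @property
    def grads(self):
        return [self.dW] + ([self.db] if self.b is not None else [])

    def forward(self, x, train=False):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        y = np.einsum("nchwpq,ocpq->nohw", win, self.W, optimize=True)
        if self.b is not None:
            y += self.b[None, :, None, None]
        if train:
            self._xp = xp
            self._in_shape = x.shape
        return y

    def backward(self, dy):
        k, s, p = self.k, self.stride, self.pad
        xp = self._xp
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self.dW[:] = np.einsum("nchwpq,nohw->ocpq", win, dy, optimize=True)
        if self.b is not None:
            self.db[:] = dy.sum(axis=(0, 2, 3))
        n, _, ho, wo = dy.shape
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                contrib = np.einsum("nohw,oc->nchw", dy, self.W[:, :, i, j],
                                    optimize=True)
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += contrib
        h, w = self._in_shape[2:]
        return dxp[:, :, p : p + h, p : p + w]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class Linear:
    """Dense layer; ``bias=False`` for CAM-compatible heads."""

    def __init__(self, d_in, d_out, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0, np.sqrt(2.0 / d_in), (d_out, d_in))
        self.b = np.zeros(d_out) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None

    @property
    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    @property
    def grads(self):
        return [self.dW] + ([self.db] if self.b is not None else [])

    def forward(self, x, train=False):
        if train:
            self._x = x
        y = x @ self.W.T
        if self.b is not None:
            y += self.b
        return y

    def backward(self, dy):
        self.dW[:] = dy.T @ self._x
        if self.b is not None:
            self.db[:] = dy.sum(axis=0)
        return dy @ self.W


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def global_avg_pool(x):
    return x.mean(axis=(2, 3))


def gap_backward(dy, spatial_shape):
    h, w = spatial_shape
    return np.broadcast_to(dy[:, :, None, None] / (h * w),
                           dy.shape + spatial_shape).copy()


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits, y):
    """Mean NLL loss and gradient w.r.t. logits for integer labels y."""
    p = softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, g / n


class SGD:
    def __init__(self, params, grads, lr, momentum=0.9):
        self.params, self.grads = params, grads
        self.lr, self.momentum = lr, momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, v in zip(self.params, self.grads, self.v):
            v *= self.momentum
            v -= self.lr * g
            p += v


class Adam:
    """Adam with bias correction; robust on short fine-tuning schedules."""

    def __init__(self, params, grads, lr, betas=(0.9, 0.999), eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
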