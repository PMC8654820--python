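"""Minimal 3-D convolutional network in numpy (forward + backprop + Adam).

Small by design: 3-D "same"-padded convolutions realized as 27 (k^3)
shifted tensordot accumulations, 2x max pooling by reshape, inverted
dropout, a global average pool and a linear head. float32 throughout;
every source of randomness comes from one Generator so training is
bit-reproducible given a seed.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "MaxPool3d", "ReLU", "Dropout", "GlobalAvgPool",
           "Dense", "Adam", "Network", "block_mean"]


def block_mean(x: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool the trailing three axes by an integer factor."""
    if factor == 1:
        return x
    *lead, d, h, w = x.shape
    if d % factor or h % factor or w % factor:
        raise ValueError(f"grid {d, h, w} not divisible by downsample factor {factor}")
    xr = x.reshape(*lead, d // factor, factor, h // factor, factor, w // factor, factor)
    return xr.mean(axis=(-5, -3, -1))


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x, training):        # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):              # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """k^3 convolution, stride 1, zero "same" padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k ** 3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, k, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training):
        k, p = self.k, self.k // 2
        bsz, _, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xp = xp
        out = np.zeros((self.w.shape[0], bsz, d, h, w), dtype=np.float32)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    patch = xp[:, :, dz:dz + d, dy:dy + h, dx:dx + w]
                    # (o,c) x (b,c,d,h,w) -> (o,b,d,h,w)
                    out += np.tensordot(self.w[:, :, dz, dy, dx], patch, axes=([1], [1]))
        out = out.transpose(1, 0, 2, 3, 4)
        return out + self.b[None, :, None, None, None]

    def backward(self, dout):
        k = self.k
        xp = self._xp
        bsz, _, d, h, w = dout.shape
        dxp = np.zeros_like(xp)
        dw, db = self.grads
        db += dout.sum(axis=(0, 2, 3, 4))
        dout_t = dout.transpose(1, 0, 2, 3, 4)     # (o,b,d,h,w)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    patch = xp[:, :, dz:dz + d, dy:dy + h, dx:dx + w]
                    dw[:, :, dz, dy, dx] += np.tensordot(
                        dout_t, patch, axes=([1, 2, 3, 4], [0, 2, 3, 4]))
                    # (c,o) x (o,b,d,h,w) -> (c,b,d,h,w)
                    contrib = np.tensordot(self.w[:, :, dz, dy, dx], dout_t,
                                           axes=([0], [0]))
                    dxp[:, :, dz:dz + d, dy:dy + h, dx:dx + w] += contrib.transpose(1, 0, 2, 3, 4)
        p = k // 2
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling; gradient split evenly among tied maxima."""

    def forward(self, x, training):
        b, c, d, h, w = x.shape
        xr = x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5, 7))
        self._mask = xr == out[:, :, :, None, :, None, :, None]
        self._counts = self._mask.sum(axis=(3, 5, 7), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, dout):
        d = dout[:, :, :, None, :, None, :, None] * self._mask / self._counts
        return d.reshape(self._shape).astype(np.float32)


class AvgPool3d(Layer):
    """2x2x2 average pooling."""

    def forward(self, x, training):
        b, c, d, h, w = x.shape
        self._shape = x.shape
        return x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))

    def backward(self, dout):
        b, c, d, h, w = self._shape
        out = np.broadcast_to(dout[:, :, :, None, :, None, :, None] / 8.0,
                              (b, c, d // 2, 2, h // 2, 2, w // 2, 2))
        return out.reshape(self._shape).astype(np.float32)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        b, c, d, h, w = self._shape
        return (np.broadcast_to(dout[:, :, None, None, None], self._shape)
                / (d * h * w)).astype(np.float32)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(1.0 / c_in), size=(c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        dw, db = self.grads
        dw += self._x.T @ dout
        db += dout.sum(axis=0)
        return dout @ self.w.T


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class Network:
    """A plain layer stack with summed scalar-output backprop."""

    def __init__(self, layers):
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0

    def forward(self, x, training: bool = False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def get_weights(self) -> list:
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w
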