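"""Minimal CPU neural-network layers with explicit forward/backward passes.

Layers are functional: ``forward`` returns ``(output, cache)`` and
``backward`` consumes that cache, so one layer instance can be used in
several forward passes of the same training step (as cyclic-GAN training
requires) before any gradient is propagated.  Parameter gradients are
accumulated into ``Param.grad``; optimizers read and clear them.

All arrays are float32, NCHW layout.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):  # -> dx
        raise NotImplementedError


def _pad_input(x: np.ndarray, pad: int, mode: str) -> np.ndarray:
    if pad == 0:
        return x
    spec = ((0, 0), (0, 0), (pad, pad), (pad, pad))
    return np.pad(x, spec, mode="reflect" if mode == "reflect" else "constant")


class Conv2d(Layer):
    """2-D convolution (cross-correlation) as a sum of per-offset GEMMs.

    For each of the k*k kernel offsets, one (out, in) x (in, N*Ho*Wo) matrix
    product is accumulated.  This keeps the working set at the size of the
    input tensor instead of materializing a k*k-fold im2col patch matrix,
    which matters on memory-bandwidth-limited CPUs.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int = 0, pad_mode: str = "zeros", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, 0.02, size=(out_ch, in_ch * k * k)).astype(np.float32)
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_ch, dtype=np.float32))
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad, self.pad_mode = pad, pad_mode

    def params(self):
        return [self.weight, self.bias]

    def _w4(self) -> np.ndarray:
        return self.weight.data.reshape(self.out_ch, self.in_ch, self.k, self.k)

    def _slab(self, xp: np.ndarray, i: int, j: int, ho: int, wo: int) -> np.ndarray:
        """Offset (i, j) view flattened to a (in_ch, N*Ho*Wo) matrix."""
        s = self.stride
        xs = xp[:, :, i:i + s * (ho - 1) + 1:s, j:j + s * (wo - 1) + 1:s]
        n = xs.shape[0]
        return np.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(
            self.in_ch, n * ho * wo)

    def forward(self, x):
        xp = _pad_input(x, self.pad, self.pad_mode)
        n, _, hp, wp = xp.shape
        ho = (hp - self.k) // self.stride + 1
        wo = (wp - self.k) // self.stride + 1
        w4 = self._w4()
        acc = np.zeros((self.out_ch, n * ho * wo), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                acc += w4[:, :, i, j] @ self._slab(xp, i, j, ho, wo)
        acc += self.bias.data[:, None]
        y = acc.reshape(self.out_ch, n, ho, wo).transpose(1, 0, 2, 3)
        return np.ascontiguousarray(y), (xp, ho, wo)

    def backward(self, dy, cache):
        xp, ho, wo = cache
        n = dy.shape[0]
        s = self.stride
        dyf = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(
            self.out_ch, n * ho * wo)
        self.bias.grad += dyf.sum(axis=1)
        w4 = self._w4()
        dw4 = self.weight.grad.reshape(self.out_ch, self.in_ch, self.k, self.k)
        dxp = np.zeros_like(xp)
        for i in range(self.k):
            for j in range(self.k):
                slab = self._slab(xp, i, j, ho, wo)
                dw4[:, :, i, j] += dyf @ slab.T
                t = (w4[:, :, i, j].T @ dyf).reshape(self.in_ch, n, ho, wo)
                dxp[:, :, i:i + s * (ho - 1) + 1:s,
                    j:j + s * (wo - 1) + 1:s] += t.transpose(1, 0, 2, 3)
        p = self.pad
        if p == 0:
            return dxp
        if self.pad_mode == "reflect":
            return _fold_reflect(dxp, p)
        return dxp[:, :, p:-p, p:-p]


def _fold_reflect(dxp: np.ndarray, p: int) -> np.ndarray:
    """Accumulate gradients of reflect-padded borders onto interior pixels.

    Reflection padding is separable, so rows are folded first (over the full
    padded width, which routes corner gradients correctly) and columns second.
    Padded row ``i < p`` mirrors interior row ``p - i``; symmetrically at the
    bottom and for columns.
    """
    tmp = dxp[:, :, p:-p, :].copy()
    for i in range(p):
        tmp[:, :, p - i, :] += dxp[:, :, i, :]
        tmp[:, :, -(p - i) - 1, :] += dxp[:, :, -(i + 1), :]
    dx = tmp[:, :, :, p:-p].copy()
    for j in range(p):
        dx[:, :, :, p - j] += tmp[:, :, :, j]
        dx[:, :, :, -(p - j) - 1] += tmp[:, :, :, -(j + 1)]
    return dx


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over spatial dims, with affine."""

    def __init__(self, ch: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch, dtype=np.float32))
        self.beta = Param(np.zeros(ch, dtype=np.float32))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        return y.astype(np.float32), (xhat, inv)

    def backward(self, dy, cache):
        xhat, inv = cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return (inv * (dxhat - m1 - xhat * m2)).astype(np.float32)


class ReLU(Layer):
    def forward(self, x):
        y = np.maximum(x, 0.0)
        return y, (x > 0)

    def backward(self, dy, cache):
        return dy * cache


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x).astype(np.float32), mask

    def backward(self, dy, cache):
        return np.where(cache, dy, self.slope * dy).astype(np.float32)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y.astype(np.float32), y

    def backward(self, dy, cache):
        return (dy * (1.0 - cache * cache)).astype(np.float32)


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x):
        y = x.repeat(2, axis=2).repeat(2, axis=3)
        return y, x.shape

    def backward(self, dy, cache):
        n, c, h, w = cache
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)).astype(np.float32)


class AvgPool2x(Layer):
    def forward(self, x):
        n, c, h, w = x.shape
        y = x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
        return y.astype(np.float32), x.shape

    def backward(self, dy, cache):
        return (dy.repeat(2, axis=2).repeat(2, axis=3) * 0.25).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x):
        caches = []
        for l in self.layers:
            x, c = l.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches):
        for l, c in zip(reversed(self.layers), reversed(caches)):
            dy = l.backward(dy, c)
        return dy


class ResidualBlock(Layer):
    """conv3-IN-ReLU-conv3-IN with an identity skip, reflect padding."""

    def __init__(self, ch: int, rng: np.random.Generator):
        self.body = Sequential(
            Conv2d(ch, ch, 3, pad=1, pad_mode="reflect", rng=rng),
            InstanceNorm2d(ch),
            ReLU(),
            Conv2d(ch, ch, 3, pad=1, pad_mode="reflect", rng=rng),
            InstanceNorm2d(ch),
        )

    def params(self):
        return self.body.params()

    def forward(self, x):
        y, c = self.body.forward(x)
        return x + y, c

    def backward(self, dy, cache):
        return dy + self.body.backward(dy, cache)
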