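"""Minimal convolutional network building blocks in numpy.

Implements exactly what the 2.5D adversarial segmenter needs — strided
convolutions via im2col, nearest-neighbour upsampling, leaky ReLU /
sigmoid, and Adam — with hand-written forward and backward passes.
Arrays are NCHW float32 throughout; every layer caches what its backward
pass needs, so a layer instance handles one forward/backward pair at a
time. Parameter gradients accumulate across backward calls until
``Adam.zero_grad``/``Adam.step``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "Upsample2x", "LeakyReLU", "Sigmoid", "InstanceNorm",
           "Adam", "bce_with_logits", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, target: float) -> float:
    """Numerically stable mean binary cross-entropy against a constant target."""
    # log(1+exp(-|z|)) + max(z,0) - z*t
    loss = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * target
    return float(loss.mean())


class Param:
    """A learnable tensor with an accumulated gradient and Adam state."""

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def _im2col(xp: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
    return cols


def _col2im(cols: np.ndarray, xp_shape, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    dxp = np.zeros(xp_shape, dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += cols[:, :, i, j]
    return dxp


class Conv2d:
    """2D convolution, stride 1 or 2, zero padding.

    Weights use He initialization (std sqrt(2 / fan_in)): without
    normalization layers in the network, a fixed small init would shrink
    activations multiplicatively per layer and kill gradient flow.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xp, k, s, ho, wo).reshape(n, c * k * k, ho * wo)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        y = np.matmul(wmat[None], cols).reshape(n, -1, ho, wo)
        y += self.b.value[None, :, None, None]
        self._cache = (cols, xp.shape, (n, c, h, w), (ho, wo))
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (n, c, h, w), (ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        cout = dy.shape[1]
        dy2 = dy.reshape(n, cout, ho * wo)
        # dW: sum over batch of dy @ cols^T
        dW = np.matmul(dy2, cols.transpose(0, 2, 1)).sum(axis=0)
        self.W.grad += dW.reshape(self.W.value.shape)
        self.b.grad += dy2.sum(axis=(0, 2))
        wmat = self.W.value.reshape(cout, -1)
        dcols = np.matmul(wmat.T[None], dy2).reshape(n, c, k, k, ho, wo)
        dxp = _col2im(dcols, xp_shape, k, s, ho, wo)
        return dxp[:, :, p : p + h, p : p + w]


class Upsample2x:
    """Nearest-neighbour x2 upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class LeakyReLU:
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class Sigmoid:
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class InstanceNorm:
    """Per-sample, per-channel normalization with learnable gain/shift.

    Keeps pre-activation distributions centred, which prevents the
    sigmoid-saturation collapse an L1-trained segmenter suffers when the
    foreground class is rare.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        m = xhat.shape[2] * xhat.shape[3]
        # standard normalization backward over the (H, W) axes
        dx = (inv / m) * (
            m * dxhat
            - dxhat.sum(axis=(2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(2, 3), keepdims=True)
        )
        return dx.astype(np.float32)


class Adam:
    """Adam with the momentum term beta1 exposed (0.5 for adversarial training)."""

    def __init__(self, params: list[Param], lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            mhat = p.m / (1 - b1**self.t)
            vhat = p.v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        self.zero_grad()
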