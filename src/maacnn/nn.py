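"""Minimal feed-forward / 1-D convolutional layers with manual backpropagation.

Everything runs in float64 on numpy so that, for a fixed seed, training is
reproducible to the bit.  Layers follow a common protocol:

* ``forward(x, training=False)`` caches whatever backward needs,
* ``backward(dy)`` accumulates parameter gradients and returns ``dx``,
* ``params()`` lists :class:`Param` objects for the optimizer.

Gradients of every layer are checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Dense", "ReLU", "Conv1d", "BatchNorm1d", "MaxPool1d",
    "Dropout", "Flatten", "Sequential", "SGDMomentum",
    "softmax", "softmax_cross_entropy", "l2_penalty", "add_l2_gradients",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map on (N, d_in) inputs, He-initialised."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 weight_scale: float | None = None):
        scale = np.sqrt(2.0 / d_in) if weight_scale is None else weight_scale
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Conv1d(Layer):
    """Same-padded 1-D convolution on (N, C, L) inputs, stride 1, odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError(f"kernel_size must be odd and positive, got {kernel_size}")
        scale = np.sqrt(2.0 / (c_in * kernel_size))
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel_size)))
        self.b = Param(np.zeros(c_out))
        self.kernel_size = kernel_size
        self.pad = kernel_size // 2

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        n, c, length = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        out = np.zeros((n, self.W.value.shape[0], length))
        for k in range(self.kernel_size):
            out += np.einsum("ncl,oc->nol", xp[:, :, k:k + length], self.W.value[:, :, k])
        out += self.b.value[None, :, None]
        self._xp, self._length = xp, length
        return out

    def backward(self, dy):
        xp, length = self._xp, self._length
        self.b.grad += dy.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        for k in range(self.kernel_size):
            self.W.grad[:, :, k] += np.einsum("nol,ncl->oc", dy, xp[:, :, k:k + length])
            dxp[:, :, k:k + length] += np.einsum("nol,oc->ncl", dy, self.W.value[:, :, k])
        p = self.pad
        return dxp[:, :, p:p + length] if p else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over the batch and spatial axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * ivar[None, :, None]
        self._cache = (xhat, ivar, training, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy):
        xhat, ivar, training, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.value[None, :, None]
        if not training:
            return dxhat * ivar[None, :, None]
        m = shape[0] * shape[2]
        sum_dxhat = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (ivar[None, :, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; trailing positions that do not fill a
    window are dropped (output length ``L // factor``)."""

    def __init__(self, factor: int):
        if factor < 1:
            raise ValueError("pool factor must be >= 1")
        self.factor = factor

    def forward(self, x, training=False):
        n, c, length = x.shape
        f = self.factor
        lp = length // f
        if lp < 1:
            raise ValueError(f"input length {length} shorter than pool factor {f}")
        xr = x[:, :, :lp * f].reshape(n, c, lp, f)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        n, c, length = self._in_shape
        f = self.factor
        lp = length // f
        dxr = np.zeros((n, c, lp, f))
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, :, :lp * f] = dxr.reshape(n, c, lp * f)
        return dx


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-300, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


def l2_penalty(weights: list[Param], lam: float) -> float:
    """``lam * sum(w**2)`` over the given weight parameters (no biases)."""
    if lam < 0:
        raise ValueError("l2 coefficient must be nonnegative")
    return float(lam * sum(float((p.value ** 2).sum()) for p in weights))


def add_l2_gradients(weights: list[Param], lam: float) -> None:
    for p in weights:
        p.grad += 2.0 * lam * p.value


class SGDMomentum:
    """Classical momentum SGD: ``v <- mu v - lr g; w <- w + v``."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
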