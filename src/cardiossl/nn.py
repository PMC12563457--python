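"""Minimal layer/backprop engine on numpy.

The study's networks are small fixed-topology CNNs, so the engine only
implements what they need: 2-D "same" convolution, 2x2 max-pooling and
nearest-neighbour up-sampling, dense layers, batch normalization, dropout,
the usual activations, row-wise L2 normalization, and Adam.  Everything is
deterministic given the ``numpy.random.Generator`` passed at build time;
forward caches are kept on the layer so a backward pass can follow any
forward pass (training or inference mode).

Layout conventions: image tensors are NHWC, dense tensors are (N, D).
Parameters default to float32; ``dtype`` can be widened to float64 for
finite-difference gradient checking.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "Dense",
    "BatchNorm",
    "MaxPool2",
    "UpSample2",
    "Flatten",
    "Dropout",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "L2Normalize",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable (or frozen) weight array with its gradient accumulator."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _init_weights(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                  fan_out: int, dtype, scheme: str = "he") -> np.ndarray:
    """He-normal for ReLU-family layers, Glorot-uniform otherwise."""
    if scheme == "he":
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(dtype)


class Conv2D(Layer):
    """k x k convolution, stride 1, zero-padded "same" output.

    Implemented as k^2 shifted matrix products, which keeps both passes as
    large GEMMs without an explicit im2col buffer.
    """

    def __init__(self, c_in: int, filters: int, kernel: int = 3, *,
                 rng: np.random.Generator, dtype=np.float32, name: str = "conv",
                 init: str = "he"):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.filters, self.kernel = c_in, filters, kernel
        w = _init_weights(rng, (kernel, kernel, c_in, filters),
                          kernel * kernel * c_in, kernel * kernel * filters,
                          dtype, init)
        self.w = Param(w, name=f"{name}.w")
        self.b = Param(np.zeros(filters, dtype=dtype), name=f"{name}.b")
        self._xp = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        k, p = self.kernel, self.kernel // 2
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        self._in_shape = x.shape
        out = np.zeros((n * h * w, self.filters), dtype=x.dtype)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di:di + h, dj:dj + w, :].reshape(-1, self.c_in)
                out += xs @ self.w.value[di, dj]
        out += self.b.value
        return out.reshape(n, h, w, self.filters)

    def backward(self, dout):
        k, p = self.kernel, self.kernel // 2
        n, h, w, _ = self._in_shape
        xp = self._xp
        d2 = dout.reshape(-1, self.filters)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di:di + h, dj:dj + w, :].reshape(-1, self.c_in)
                self.w.grad[di, dj] += xs.T @ d2
                dxp[:, di:di + h, dj:dj + w, :] += (
                    d2 @ self.w.value[di, dj].T).reshape(n, h, w, self.c_in)
        self.b.grad += d2.sum(axis=0)
        if p == 0:
            return dxp
        return dxp[:, p:-p, p:-p, :]


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, *, rng: np.random.Generator,
                 dtype=np.float32, name: str = "dense", init: str = "he"):
        self.d_in, self.d_out = d_in, d_out
        self.w = Param(_init_weights(rng, (d_in, d_out), d_in, d_out, dtype,
                                     init), name=f"{name}.w")
        self.b = Param(np.zeros(d_out, dtype=dtype), name=f"{name}.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class BatchNorm(Layer):
    """Channel-wise batch normalization (last axis).

    gamma/beta are trainable; the running moments are the non-trainable
    parameters, updated with exponential momentum during training and used
    verbatim at inference.
    """

    def __init__(self, channels: int, *, momentum: float = 0.99,
                 eps: float = 1e-3, dtype=np.float32, name: str = "bn"):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), name=f"{name}.beta")
        self.running_mean = Param(np.zeros(channels, dtype=dtype),
                                  trainable=False, name=f"{name}.moving_mean")
        self.running_var = Param(np.ones(channels, dtype=dtype),
                                 trainable=False, name=f"{name}.moving_var")

    def params(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean.value[:] = m * self.running_mean.value + (1 - m) * mean
            self.running_var.value[:] = m * self.running_var.value + (1 - m) * var
        else:
            mean = self.running_mean.value
            var = self.running_var.value
        self._train = train
        self._axes = axes
        self._n = x.size // x.shape[-1]
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout):
        axes = self._axes
        self.gamma.grad += (dout * self._xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value * self._inv
        if not self._train:
            return dout * g
        n = self._n
        dxhat = dout * self.gamma.value
        return self._inv / n * (
            n * dxhat
            - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )


class MaxPool2(Layer):
    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = xr.reshape(n, h // 2, w // 2, c, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._shape
        g = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(g, self._idx[..., None], dout[..., None], axis=-1)
        return (g.reshape(n, h // 2, w // 2, c, 2, 2)
                 .transpose(0, 1, 4, 2, 5, 3)
                 .reshape(n, h, w, c))


class UpSample2(Layer):
    """Nearest-neighbour 2x up-sampling."""

    def forward(self, x, train=False, rng=None):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        self._mask = self._mask.astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Sigmoid(Layer):
    def forward(self, x, train=False, rng=None):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        e = np.exp(x[~pos])
        out[~pos] = e / (1.0 + e)
        self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class L2Normalize(Layer):
    """Row-wise projection onto the unit sphere (contrastive embeddings)."""

    def __init__(self, eps: float = 1e-12):
        self.eps = eps

    def forward(self, x, train=False, rng=None):
        norm = np.sqrt((x * x).sum(axis=1, keepdims=True)) + self.eps
        self._z = x / norm
        self._norm = norm
        return self._z

    def backward(self, dout):
        z = self._z
        return (dout - z * (z * dout).sum(axis=1, keepdims=True)) / self._norm


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout, start: int | None = None) -> np.ndarray:
        """Backpropagate ``dout``; ``start`` skips trailing layers.

        ``start=-2`` begins at the penultimate layer, which lets callers fuse
        a sigmoid output with a cross-entropy loss for numerical stability.
        """
        layers = self.layers if start is None else self.layers[:start + 1 or None]
        for layer in reversed(layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[:] = 0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value[:] = w

    def checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.params():
            h.update(np.ascontiguousarray(p.value, dtype=np.float32).tobytes())
        return h.hexdigest()


class Adam:
    """Adam with the standard bias correction (Kingma & Ba defaults except lr)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
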