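"""Minimal trainable neural-network core on numpy arrays.

Implements exactly the pieces the slide-genotype pipeline needs: strided
"patchify" convolutions, batch normalisation with a switchable inference mode
(batch statistics vs. exponentially decaying running statistics), dense
layers, dropout, global average pooling, the softmax/sigmoid activations and
their cross-entropy losses, and the Adam optimiser.

Layers operate on channels-last arrays (``(N, H, W, C)`` for images,
``(N, C)`` for feature matrices).  Every layer exposes ``forward(x, mode)``
and ``backward(grad)``; parameters are held in :class:`Param` objects so an
optimiser can update them in place.

Modes:

``"train"``
    batch statistics are used and running statistics updated; dropout active.
``"eval_batch"``
    batch statistics of the presented batch are used for normalisation
    (one-slide-per-batch inference); dropout inactive.
``"eval_moving"``
    the running mean/variance tracked during training are used.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_MODES = ("train", "eval_batch", "eval_moving")


# ---------------------------------------------------------------------------
# activations and losses
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stabilised softmax along ``axis``.

    Shift-invariant: ``softmax(z + c) == softmax(z)`` for any constant ``c``,
    so arbitrarily large logits do not overflow.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    shifted = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def sigmoid(z):
    """Logistic function g(z) = 1 / (1 + exp(-z)), stable for large |z|."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("sigmoid requires finite input")
    return expit(z)


def categorical_cross_entropy(probs, targets, reduction: str = "mean",
                              eps: float = 1e-12):
    """Cross-entropy  l = -sum_j y_j log p_j  for one-hot ``targets``.

    ``probs`` rows must lie on the probability simplex; values are clipped at
    ``eps`` before the log so a confident correct prediction gives exactly 0
    and a zero probability on the target class stays finite.
    """
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.atleast_2d(np.asarray(targets, dtype=float))
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs targets {y.shape}")
    if np.any(p < -eps) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probs rows must be points on the probability simplex")
    per_example = -np.sum(y * np.log(np.clip(p, eps, 1.0)), axis=1)
    return _reduce(per_example, reduction)


def binary_cross_entropy(p, y, reduction: str = "mean", eps: float = 1e-12):
    """Binary cross-entropy  l = -(y log p + (1-y) log(1-p)).

    The batch loss may be aggregated by summing or averaging; ``reduction``
    selects ``"mean"``, ``"sum"`` or ``"none"``.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    p = np.clip(p, eps, 1.0 - eps)
    per_example = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return _reduce(per_example, reduction)


def _reduce(values, reduction):
    if reduction == "mean":
        return float(values.mean())
    if reduction == "sum":
        return float(values.sum())
    if reduction == "none":
        return values
    raise ValueError(f"unknown reduction {reduction!r}")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class PatchifyConv(Layer):
    """k x k convolution with stride k (non-overlapping windows).

    Because windows do not overlap, the backward pass to the input is a pure
    reshape, which keeps pure-numpy training fast.  Stacking these blocks
    grows the receptive field geometrically (k, k^2, ...).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        self.c_in = c_in
        fan_in = k * k * c_in
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, mode="train"):
        n, h, w, c = x.shape
        k = self.k
        if c != self.c_in or h % k or w % k:
            raise ValueError(
                f"PatchifyConv expects (N, H, W, {self.c_in}) with H, W "
                f"divisible by {k}; got {x.shape}")
        self._in_shape = x.shape
        cols = (x.reshape(n, h // k, k, w // k, k, c)
                 .transpose(0, 1, 3, 2, 4, 5)
                 .reshape(-1, k * k * c))
        self._cols = cols
        out = cols @ self.w.value + self.b.value
        return out.reshape(n, h // k, w // k, -1)

    def backward(self, grad):
        n, ho, wo, co = grad.shape
        g = grad.reshape(-1, co)
        self.w.grad += self._cols.T @ g
        self.b.grad += g.sum(axis=0)
        k, c = self.k, self.c_in
        dcols = g @ self.w.value.T
        return (dcols.reshape(n, ho, wo, k, k, c)
                     .transpose(0, 1, 3, 2, 4, 5)
                     .reshape(self._in_shape))


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, mode="train"):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, mode="train"):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Tanh(Layer):
    def forward(self, x, mode="train"):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y ** 2)


class BatchNorm(Layer):
    """Normalisation over all but the channel (last) axis.

    In ``train`` mode batch statistics are used and the exponentially
    decaying running statistics updated; ``eval_batch`` normalises with the
    statistics of the presented batch itself (the one-slide-per-batch
    inference mode); ``eval_moving`` uses the running statistics.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, mode="train"):
        if mode not in _MODES:
            raise ValueError(f"unknown mode {mode!r}")
        c = x.shape[-1]
        flat = x.reshape(-1, c)
        if mode == "eval_moving":
            mean, var = self.running_mean, self.running_var
        else:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            if mode == "train":
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mean
                self.running_var = (1 - m) * self.running_var + m * var
        std = np.sqrt(var + self.eps)
        xhat = (flat - mean) / std
        self._xhat, self._std, self._shape = xhat, std, x.shape
        out = self.gamma.value * xhat + self.beta.value
        return out.reshape(x.shape)

    def backward(self, grad):
        c = grad.shape[-1]
        dy = grad.reshape(-1, c)
        xhat, std = self._xhat, self._std
        m = dy.shape[0]
        self.beta.grad += dy.sum(axis=0)
        self.gamma.grad += (dy * xhat).sum(axis=0)
        dxhat = dy * self.gamma.value
        dx = (dxhat - dxhat.mean(axis=0)
              - xhat * (dxhat * xhat).mean(axis=0)) / std
        return dx.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, mode="train"):
        if mode != "train" or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class GlobalAvgPool(Layer):
    """(N, H, W, C) -> (N, C) spatial mean."""

    def forward(self, x, mode="train"):
        self._spatial = x.shape[1] * x.shape[2]
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / self._spatial,
                               self._shape).copy()


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, mode="train"):
        for layer in self.layers:
            x = layer.forward(x, mode)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def small_cnn(channels=(8, 16, 32), k=2, c_in: int = 3,
              rng: np.random.Generator | None = None) -> Sequential:
    """Compact convolutional feature extractor ending in global average
    pooling; output dimension is ``channels[-1]``.

    ``k`` is a single window/stride or a per-block schedule (e.g.
    ``(4, 2, 2)``); input sides must be divisible by the product of the
    strides, so the same architecture serves full-size 224 px inputs and
    reduced desk-scale ones.
    """
    rng = np.random.default_rng() if rng is None else rng
    ks = (k,) * len(channels) if np.isscalar(k) else tuple(k)
    if len(ks) != len(channels):
        raise ValueError("need one stride per conv block")
    layers: list[Layer] = []
    prev = c_in
    for c, ki in zip(channels, ks):
        layers += [PatchifyConv(prev, c, ki, rng), BatchNorm(c), ReLU()]
        prev = c
    layers.append(GlobalAvgPool())
    return Sequential(layers)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def get_weights(layer: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in layer.params()]


def set_weights(layer: Layer, weights: list[np.ndarray]) -> None:
    for p, w in zip(layer.params(), weights):
        p.value[...] = w
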