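"""Minimal feed-forward neural-network core for the pulse detector.

Implements exactly the pieces the detector architecture needs — 3x3 same
convolutions, ReLU, 2x2 max pooling, global average pooling, dense layers,
inverted dropout, softmax cross-entropy, Glorot-uniform initialisation and
an Adam optimizer with staircase exponential learning-rate decay — on
plain numpy arrays in NHWC layout.  CPU-sized by design: the detector's
default backbone is a few thousand convolution weights, so vectorised
numpy is entirely adequate for desk-scale training runs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "Dropout",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "staircase_lr",
]


_DTYPE = np.float32  # single precision: ample for SGD, twice the throughput


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


class Layer:
    """Base layer; params/grads are parallel lists of arrays."""

    params: list
    grads: list

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (configurable) same-padding convolution, stride 1, NHWC."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in, fan_out = k * k * in_ch, k * k * out_ch
        self.k = k
        self.W = glorot_uniform(rng, (k, k, in_ch, out_ch), fan_in, fan_out)
        self.b = np.zeros(out_ch, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, p = self.k, self.k // 2
        xpad = np.pad(x.astype(_DTYPE, copy=False), ((0, 0), (p, p), (p, p), (0, 0)))
        self._xpad = xpad
        n, hp, wp, _ = xpad.shape
        h, w = hp - 2 * p, wp - 2 * p
        out = np.broadcast_to(self.b, (n, h, w, self.b.size)).copy()
        for di in range(k):
            for dj in range(k):
                out += xpad[:, di : di + h, dj : dj + w, :] @ self.W[di, dj]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xpad = self._xpad
        n, hp, wp, _ = xpad.shape
        h, w = hp - 2 * p, wp - 2 * p
        dxpad = np.zeros_like(xpad)
        dW, db = self.grads
        dW[...] = 0.0
        db[...] = dout.sum(axis=(0, 1, 2))
        for di in range(k):
            for dj in range(k):
                patch = xpad[:, di : di + h, dj : dj + w, :]
                dW[di, dj] = np.einsum("nhwc,nhwf->cf", patch, dout)
                dxpad[:, di : di + h, dj : dj + w, :] += dout @ self.W[di, dj].T
        return dxpad[:, p : p + h, p : p + w, :] if p else dxpad


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """k x k max pooling, stride k; trailing partial rows/cols are dropped."""

    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        n, h, w, c = x.shape
        h2, w2 = h // k, w // k
        xr = x[:, : h2 * k, : w2 * k, :].reshape(n, h2, k, w2, k, c)
        windows = xr.transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, k * k, c)
        self._argmax = windows.argmax(axis=3)
        self._in_shape = x.shape
        return windows.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        n, h, w, c = self._in_shape
        h2, w2 = h // k, w // k
        dwin = np.zeros((n, h2, w2, k * k, c), dtype=dout.dtype)
        np.put_along_axis(dwin, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, : h2 * k, : w2 * k, :] = (
            dwin.reshape(n, h2, w2, k, k, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h2 * k, w2 * k, c)
        )
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(dout[:, None, None, :], (n, h, w, c)) / (h * w)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.W = glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim)
        self.b = np.zeros(out_dim, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class Dropout(Layer):
    """Inverted dropout: active only in training mode; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list:
        return [g for layer in self.layers for g in layer.grads]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(onehot * np.log(np.clip(p, 1e-12, None))) / n
    return loss, (p - onehot) / n


def staircase_lr(step: int, initial: float = 1e-3, decay: float = 0.75, decay_steps: int = 90) -> float:
    """Exponential decay with a staircase: initial * decay**floor(step/decay_steps)."""
    return initial * decay ** (step // decay_steps)


class Adam:
    """Adaptive-moment estimation; the learning rate is supplied per step."""

    def __init__(self, params: list, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
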