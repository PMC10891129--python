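"""A compact NumPy convolutional network with explicit backpropagation.

Just enough machinery for the transfer-learning protocol: 3x3 "same"
convolutions (im2col), ReLU, 2x2 max pooling, global average pooling,
dense layers, inverted dropout and a softmax cross-entropy loss, plus
mini-batch SGD / RMSprop / Adam trainers. Data layout is NCHW float32.

Every layer owns its parameter dict, gradient dict and a ``trainable``
flag; the trainers skip frozen layers entirely, so frozen weights stay
bit-identical through training.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "Dropout",
    "softmax",
    "softmax_cross_entropy",
    "train_layers",
    "forward_layers",
]


class Layer:
    trainable: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """k×k convolution with 'same' zero padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.params["W"] = (rng.standard_normal((c_out, fan_in)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x, train, rng):
        n, c, h, w = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        self._cols = cols if train else None
        self._shape = (n, c, h, w)
        out = cols @ self.params["W"].T + self.params["b"]
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, c, h, w = self._shape
        k = self.k
        p = k // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.grads["W"] = (dflat.T @ self._cols).astype(np.float32)
        self.grads["b"] = dflat.sum(axis=0).astype(np.float32)
        dcols = (dflat @ self.params["W"]).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        d6 = dcols.transpose(0, 3, 4, 5, 1, 2)  # n, c, k, k, h, w
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + h, kj : kj + w] += d6[:, :, ki, kj]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x, train, rng):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 needs even spatial dimensions")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._idx = win.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dwin, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dwin.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class GlobalAvgPool(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).astype(np.float32)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params["W"] = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(d_out, dtype=np.float32)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = (self._x.T @ dout).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
    return loss, ((p - onehot) / n).astype(np.float32)


def forward_layers(
    layers: Sequence[Layer], x: np.ndarray, train: bool = False, rng=None
) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, train, rng)
    return x


def _trainable_params(layers: Sequence[Layer]):
    for layer in layers:
        if layer.trainable:
            for name in layer.params:
                yield layer, name


def train_layers(
    layers: Sequence[Layer],
    x: np.ndarray,
    onehot: np.ndarray,
    *,
    optimizer: str = "ADAM",
    learning_rate: float = 1e-3,
    epochs: int = 10,
    batch_size: int = 32,
    seed: int = 0,
) -> list[float]:
    """Mini-batch training of the trainable layers; returns per-epoch losses.

    Frozen layers (``trainable=False``) still propagate gradients but
    their parameters are never touched.
    """
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    state: dict[tuple[int, str], dict[str, np.ndarray]] = {}
    step = 0
    history: list[float] = []
    n = len(x)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            out = forward_layers(layers, x[idx], train=True, rng=drop_rng)
            loss, dout = softmax_cross_entropy(out, onehot[idx])
            epoch_loss += loss * len(idx)
            for layer in reversed(layers):
                dout = layer.backward(dout)
            step += 1
            for layer, name in _trainable_params(layers):
                g = layer.grads[name]
                p = layer.params[name]
                key = (id(layer), name)
                if optimizer == "SGD":
                    p -= learning_rate * g
                elif optimizer == "RMSPROP":
                    st = state.setdefault(key, {"v": np.zeros_like(p)})
                    st["v"][:] = 0.9 * st["v"] + 0.1 * g * g
                    p -= learning_rate * g / np.sqrt(st["v"] + 1e-6)
                elif optimizer == "ADAM":
                    st = state.setdefault(key, {"m": np.zeros_like(p), "v": np.zeros_like(p)})
                    st["m"][:] = 0.9 * st["m"] + 0.1 * g
                    st["v"][:] = 0.999 * st["v"] + 0.001 * g * g
                    mh = st["m"] / (1.0 - 0.9**step)
                    vh = st["v"] / (1.0 - 0.999**step)
                    p -= learning_rate * mh / (np.sqrt(vh) + 1e-8)
                else:
                    raise ValueError(f"unknown optimizer {optimizer!r}")
        history.append(epoch_loss / n)
    return history
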