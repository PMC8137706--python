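"""Minimal numpy neural networks for the FNN/CNN classifier families.

Implements exactly the layer set the benchmark architectures need — dense,
2-D convolution with 'same' spatial padding, max-pooling with stride equal
to pool size ('valid' boundary), batch normalization, dropout, ReLU and
sigmoid — plus Adam and a class-weighted binary cross-entropy. Everything
is float32 and deterministic given a seed.

Architecture catalogue (trainable + batch-norm running statistics):

====== ==========================================================
FNN1   5457 -> 1000 -> 100 -> 1           (5,558,201 parameters)
FNN2   5457 -> 1000 -> 500 -> 100 -> 1    (6,008,701 parameters)
CNN1   Conv20(21x11) -> pool(3,2) -> BN -> Dense100 -> 1
       (1,754,921 parameters)
CNN2   Conv20(21x11) -> pool(3,2) -> Conv40(11x7) -> Conv60(3x3)
       -> Dense100 -> 1, BN after every conv  (5,338,621 parameters)
====== ==========================================================

ReLU in hidden layers, sigmoid output, dropout 0.2 (0.25 before the CNN2
output block).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .grids import N_FREQ, N_PRESS

DTYPE = np.float32


class Layer:
    """Base layer: params/grads are parallel lists of float32 arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def init(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        """Trainable + non-trainable parameter count."""
        return int(sum(p.size for p in self.params))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.w = np.zeros((n_in, n_out), dtype=DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def init(self, rng: np.random.Generator) -> None:
        # He initialization (hidden layers are ReLU)
        self.w[...] = rng.normal(0.0, math.sqrt(2.0 / self.n_in), self.w.shape).astype(DTYPE)
        self.b[...] = 0.0

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Conv2D(Layer):
    """2-D convolution, NHWC layout, 'same' spatial padding, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.kh, self.kw = in_ch, out_ch, kh, kw
        self.w = np.zeros((in_ch * kh * kw, out_ch), dtype=DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.first_layer = False  # set by the model; skips unused input grads

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.in_ch * self.kh * self.kw
        self.w[...] = rng.normal(0.0, math.sqrt(2.0 / fan_in), self.w.shape).astype(DTYPE)
        self.b[...] = 0.0

    def forward(self, x, train, rng):
        n, h, w, _ = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        # (n, h, w, c, kh, kw) view over the padded input
        windows = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        cols = windows.transpose(0, 1, 2, 3, 4, 5).reshape(n * h * w, -1)
        self._cols = np.ascontiguousarray(cols, dtype=DTYPE)
        self._shape = (n, h, w)
        out = self._cols @ self.w + self.b
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, grad):
        n, h, w = self._shape
        gm = grad.reshape(n * h * w, self.out_ch)
        self.grads[0][...] = self._cols.T @ gm
        self.grads[1][...] = gm.sum(axis=0)
        if self.first_layer:
            return None
        ph, pw = self.kh // 2, self.kw // 2
        dcols = (gm @ self.w.T).reshape(n, h, w, self.in_ch, self.kh, self.kw)
        dxp = np.zeros((n, h + 2 * ph, w + 2 * pw, self.in_ch), dtype=DTYPE)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, :, i, j]
        return dxp[:, ph : ph + h, pw : pw + w, :]


class MaxPool2D(Layer):
    """Max pooling with stride == pool size and 'valid' boundary."""

    def __init__(self, ph: int, pw: int) -> None:
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x, train, rng):
        n, h, w, c = x.shape
        ho, wo = h // self.ph, w // self.pw
        xr = x[:, : ho * self.ph, : wo * self.pw, :].reshape(n, ho, self.ph, wo, self.pw, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        # split gradient equally among tied maxima
        self._mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
        self._in_shape = (n, h, w, c)
        return out

    def backward(self, grad):
        n, h, w, c = self._in_shape
        ho, wo = h // self.ph, w // self.pw
        dxr = self._mask * grad[:, :, None, :, None, :]
        dx = np.zeros((n, h, w, c), dtype=DTYPE)
        dx[:, : ho * self.ph, : wo * self.pw, :] = dxr.reshape(n, ho * self.ph, wo * self.pw, c)
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis.

    gamma/beta are trainable; running mean/variance are the non-trainable
    statistics used at inference (all four count toward the parameter
    total, 4 per channel).
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.params = [self.gamma, self.beta, self.running_mean, self.running_var]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum, self.eps = momentum, eps

    @property
    def trainable(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    def forward(self, x, train, rng):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._inv_sd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self._xhat = ((x - mean) * self._inv_sd).astype(DTYPE)
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = self._axes
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        m = self._m
        g = grad * self.gamma
        return self._inv_sd * (
            g - g.mean(axis=axes) - self._xhat * (g * self._xhat).mean(axis=axes)
        )


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train, rng):
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate).astype(DTYPE) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def _pooled(h: int, w: int, ph: int, pw: int) -> tuple[int, int]:
    return h // ph, w // pw


def make_layers(arch_id: str) -> list[Layer]:
    """Instantiate the layer stack of one catalogued architecture."""
    ph, pw = _pooled(N_FREQ, N_PRESS, 3, 2)  # 35 x 25 after the shared first pool
    if arch_id == "FNN1":
        return [
            Dense(N_FREQ * N_PRESS, 1000), ReLU(), Dropout(0.2),
            Dense(1000, 100), ReLU(), Dropout(0.2),
            Dense(100, 1), Sigmoid(),
        ]
    if arch_id == "FNN2":
        return [
            Dense(N_FREQ * N_PRESS, 1000), ReLU(), Dropout(0.2),
            Dense(1000, 500), ReLU(), Dropout(0.2),
            Dense(500, 100), ReLU(), Dropout(0.2),
            Dense(100, 1), Sigmoid(),
        ]
    if arch_id == "CNN1":
        return [
            Conv2D(1, 20, 21, 11), MaxPool2D(3, 2), BatchNorm(20), ReLU(),
            Flatten(), Dense(ph * pw * 20, 100), ReLU(), Dropout(0.2),
            Dense(100, 1), Sigmoid(),
        ]
    if arch_id == "CNN2":
        return [
            Conv2D(1, 20, 21, 11), MaxPool2D(3, 2), BatchNorm(20), ReLU(), Dropout(0.2),
            Conv2D(20, 40, 11, 7), BatchNorm(40), ReLU(), Dropout(0.2),
            Conv2D(40, 60, 3, 3), BatchNorm(60), ReLU(), Dropout(0.2),
            Flatten(), Dense(ph * pw * 60, 100), ReLU(), Dropout(0.25),
            Dense(100, 1), Sigmoid(),
        ]
    raise ValueError(f"unknown architecture id {arch_id!r}")


def count_parameters(arch_id: str) -> int:
    """Total parameter count (weights, biases, and batch-norm statistics)."""
    return int(sum(layer.n_params for layer in make_layers(arch_id)))


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    val_fraction: float = 0.1  # held out of the training fold for early stopping
    patience: int = 10  # epochs without val-loss improvement; 0 disables


class NeuralNet:
    """A sequential network with Adam and weighted binary cross-entropy."""

    def __init__(self, arch_id: str, seed: int = 0) -> None:
        self.arch_id = arch_id
        self.layers = make_layers(arch_id)
        self.rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init(self.rng)
        for layer in self.layers:
            if isinstance(layer, Conv2D):
                layer.first_layer = layer is self.layers[0]
        self.is_conv = any(isinstance(l, Conv2D) for l in self.layers)
        if not isinstance(self.layers[-1], Sigmoid):
            raise ValueError("output layer must be sigmoid")
        self._adam_state: list[tuple[np.ndarray, np.ndarray]] | None = None
        self._adam_t = 0

    # -- parameter bookkeeping -------------------------------------------
    def _trainable(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                pairs.extend(zip(layer.trainable, layer.grads))
            else:
                pairs.extend(zip(layer.params, layer.grads))
        return pairs

    @property
    def n_params(self) -> int:
        return int(sum(layer.n_params for layer in self.layers))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = weights[i]
                i += 1

    # -- forward / backward ----------------------------------------------
    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=DTYPE)
        if self.is_conv and X.ndim == 2:
            X = X.reshape(-1, N_FREQ, N_PRESS, 1)
        elif not self.is_conv and X.ndim > 2:
            X = X.reshape(X.shape[0], -1)
        return X

    def _forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        out = X
        for layer in self.layers:
            out = layer.forward(out, train, self.rng)
        return out

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = self._prepare(X)
        chunks = [
            self._forward(X[i : i + batch_size], train=False).ravel()
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(chunks).astype(float)

    def _adam_step(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        pairs = self._trainable()
        if self._adam_state is None:
            self._adam_state = [(np.zeros_like(p), np.zeros_like(p)) for p, _ in pairs]
        self._adam_t += 1
        t = self._adam_t
        for (p, g), (m, v) in zip(pairs, self._adam_state):
            m[...] = beta1 * m + (1 - beta1) * g
            v[...] = beta2 * v + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p[...] = p - lr * mhat / (np.sqrt(vhat) + eps)

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
        p = np.clip(p, 1e-7, 1 - 1e-7)
        return float(np.mean(w * -(y * np.log(p) + (1 - y) * np.log(1 - p))))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        sample_weight: np.ndarray | None = None,
        config: TrainConfig | None = None,
    ) -> "NeuralNet":
        """Minimize weighted binary cross-entropy with Adam.

        With ``val_fraction > 0`` and ``patience > 0``, a random slice of
        the training data is held out, training stops after ``patience``
        epochs without validation-loss improvement, and the best weights
        are restored.
        """
        cfg = config or TrainConfig()
        X = self._prepare(X)
        y = np.asarray(y, dtype=DTYPE).ravel()
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, dtype=DTYPE)

        n_val = int(round(cfg.val_fraction * X.shape[0])) if cfg.patience > 0 else 0
        idx = self.rng.permutation(X.shape[0])
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        if n_val and (len(np.unique(y[val_idx])) < 2 or len(np.unique(y[tr_idx])) < 2):
            n_val, tr_idx, val_idx = 0, idx, idx[:0]  # degenerate split; train on all
        Xt, yt, wt = X[tr_idx], y[tr_idx], w[tr_idx]

        best_loss, best_weights, stall = np.inf, None, 0
        for _ in range(cfg.epochs):
            order = self.rng.permutation(Xt.shape[0])
            for start in range(0, Xt.shape[0], cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                xb, yb, wb = Xt[batch], yt[batch], wt[batch]
                probs = self._forward(xb, train=True).ravel()
                # fused sigmoid + BCE gradient w.r.t. the pre-sigmoid logits
                dlogits = ((probs - yb) * wb / xb.shape[0]).astype(DTYPE)
                grad = dlogits.reshape(-1, 1)
                for layer in reversed(self.layers[:-1]):
                    grad = layer.backward(grad)
                self._adam_step(cfg.learning_rate)
            if n_val:
                val_loss = self._bce(self.predict_proba(X[val_idx]), y[val_idx], w[val_idx])
                if val_loss < best_loss - 1e-6:
                    best_loss, best_weights, stall = val_loss, self.get_weights(), 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
        if best_weights is not None:
            self.set_weights(best_weights)
        return self
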