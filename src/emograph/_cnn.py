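"""Minimal 1-D convolutional network in numpy.

Three valid-padding conv blocks (conv -> ReLU -> max-pool) over a
single-channel sequence, a ReLU dense layer and a logistic output unit,
trained with Adam on binary cross-entropy.  Written against float64 so the
backward pass can be verified by numerical differentiation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv1D", "ReLU", "MaxPool1D", "Flatten", "Dense", "Network", "Adam"]


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1D(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, C_in, L) -> (B, C_out, L - k + 1)
        self._cols = sliding_window_view(x, self.kernel, axis=2)
        return (
            np.einsum("bilk,oik->bol", self._cols, self.W, optimize=True)
            + self.b[:, None]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("bol,bilk->oik", dy, self._cols, optimize=True)
        self.db = dy.sum(axis=(0, 2))
        k = self.kernel
        padded = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
        windows = sliding_window_view(padded, k, axis=2)
        return np.einsum("botj,oij->bit", windows, self.W[:, :, ::-1], optimize=True)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1D(Layer):
    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        keep = (length // self.pool) * self.pool
        self._in_shape = x.shape
        blocks = x[:, :, :keep].reshape(b, c, -1, self.pool)
        self._argmax = blocks.argmax(axis=3)
        return blocks.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, lout = dy.shape
        dx = np.zeros(self._in_shape)
        blocks = dx[:, :, : lout * self.pool].reshape(b, c, lout, self.pool)
        bi, ci, li = np.ogrid[:b, :c, :lout]
        blocks[bi, ci, li, self._argmax] = dy
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Network:
    """Sequential layers ending in a single logit; BCE-with-logits loss."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits[:, None]
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    n = logits.size
    # log(1 + exp(-|z|)) formulation avoids overflow
    loss = float(np.mean(np.maximum(logits, 0) - logits * y
                         + np.log1p(np.exp(-np.abs(logits)))))
    p = 1.0 / (1.0 + np.exp(-logits))
    return loss, (p - y) / n


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
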