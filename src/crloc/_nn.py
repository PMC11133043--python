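"""Minimal NumPy convolutional-network engine.

Implements exactly the pieces the CR regressor needs — 3x3 same-padding
convolutions, ReLU, 2x2 max pooling, dense layers, mean-squared-error loss
and the Adam optimizer — with explicit backpropagation in float32.  Layers
carry a ``trainable`` flag so whole blocks can be frozen during fine
tuning.  Inference and training are deterministic given the initialization
generator and the data stream.

Data layout is channels-last: ``(N, H, W, C)``.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

F32 = np.float32


class Layer:
    trainable: bool = True

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W,k*k*C) patches with zero same-padding."""
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = np.empty((n, h, w, k * k, c), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i * k + j, :] = xp[:, i : i + h, j : j + w, :]
    return cols.reshape(n, h, w, k * k * c)


def _col2im(dcols: np.ndarray, x_shape: Tuple[int, ...], k: int) -> np.ndarray:
    n, h, w, c = x_shape
    p = k // 2
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dcols.dtype)
    dcols = dcols.reshape(n, h, w, k * k, c)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i * k + j, :]
    return dxp[:, p : p + h, p : p + w, :]


class Conv2D(Layer):
    """3x3 (by default) convolution, stride 1, zero same-padding, He init."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.k = k
        fan_in = k * k * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = _im2col(x, self.k).reshape(n * h * w, -1)
        if train:
            self._cols = cols
            self._x_shape = x.shape
        out = cols @ self.W + self.b
        return out.reshape(n, h, w, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c_out = grad.shape
        g = grad.reshape(n * h * w, c_out)
        if self.trainable:
            self.dW = self._cols.T @ g
            self.db = g.sum(axis=0)
        dcols = g @ self.W.T
        dx = _col2im(dcols.reshape(n, h, w, -1), self._x_shape, self.k)
        self._cols = None
        return dx

    def params(self) -> List[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> List[np.ndarray]:
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        out = xc.max(axis=(2, 4))
        if train:
            self._x_shape = x.shape
            self._mask = xc == out[:, :, None, :, None, :]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, h, w, c), dtype=grad.dtype)
        g = self._mask * grad[:, :, None, :, None, :]
        dx[:, : 2 * h2, : 2 * w2, :] = g.reshape(n, 2 * h2, 2 * w2, c)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        bias_init: Optional[Sequence[float]] = None,
    ):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(F32)
        self.b = (
            np.asarray(bias_init, dtype=F32)
            if bias_init is not None
            else np.zeros(n_out, dtype=F32)
        )
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.trainable:
            self.dW = self._x.T @ grad
            self.db = grad.sum(axis=0)
        dx = grad @ self.W.T
        self._x = None
        return dx

    def params(self) -> List[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> List[np.ndarray]:
        return [self.dW, self.db]


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def trainable_params(self) -> Tuple[List[np.ndarray], List[np.ndarray]]:
        ps, gs = [], []
        for layer in self.layers:
            if layer.trainable:
                ps.extend(layer.params())
                gs.extend(layer.grads())
        return ps, gs

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for p in layer.params():
                w = next(it)
                if p.shape != w.shape:
                    raise ValueError(
                        f"weight shape mismatch: {p.shape} vs {w.shape}"
                    )
                p[...] = w


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8
    ):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            key = id(p)
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean squared error over all coordinates and its gradient w.r.t. pred."""
    diff = (pred - target).astype(F32)
    loss = float(np.mean(diff**2))
    grad = (2.0 / diff.size) * diff
    return loss, grad
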