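"""A small, fully seeded feed-forward neural-network engine on numpy.

Provides exactly the pieces the gait regressors need: dense and 2-D
convolutional layers (im2col-based), ReLU/sigmoid activations, max
pooling, RMSE and MSE losses, and SGD/Adam optimizers.  Everything is
float64 and deterministic given the initialization and shuffling
generators, so trained models are bit-reproducible on a fixed machine.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense", "ReLU", "Sigmoid", "Flatten", "Conv2D", "MaxPool2D",
    "MSELoss", "RMSELoss", "SGD", "Adam", "Network", "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                    shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        super().__init__()
        self.w = _glorot_uniform(rng, n_in, n_out, (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Conv2D(Layer):
    """2-D convolution over NCHW input, implemented via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, pad: int = 0,
                 dtype=np.float64) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        self.w = _glorot_uniform(rng, fan_in, fan_out,
                                 (c_out, c_in, kernel, kernel)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho, wo = self.out_size(h, w)
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # n, c, ho, wo, k, k -> (n*ho*wo, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        self._cols, self._xshape, self._hw = cols, x.shape, (n, ho, wo)
        wmat = self.w.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.b
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, ho, wo = self._hw
        k, s, p = self.k, self.stride, self.pad
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        wmat = self.w.reshape(self.c_out, -1)
        self.grads[0][...] = (dmat.T @ self._cols).reshape(self.w.shape)
        self.grads[1][...] = dmat.sum(axis=0)
        dcols = (dmat @ wmat).reshape(n, ho, wo, self.c_in, k, k)
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx


class MaxPool2D(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2) -> None:
        super().__init__()
        self.k, self.stride = kernel, stride

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        return (h - self.k) // self.stride + 1, (w - self.k) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        ho, wo = self.out_size(h, w)
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(n, c, ho, wo, k * k)
        self._argmax = flat.argmax(axis=-1)
        self._xshape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, s = self.k, self.stride
        ho, wo = dout.shape[2], dout.shape[3]
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        ni, ci, hi, wi = np.ix_(np.arange(n), np.arange(c), np.arange(ho), np.arange(wo))
        rows = hi * s + self._argmax // k
        cols = wi * s + self._argmax % k
        np.add.at(dx, (np.broadcast_to(ni, rows.shape), np.broadcast_to(ci, rows.shape),
                       rows, cols), dout)
        return dx


class MSELoss:
    """Mean squared error over the whole batch."""

    def value_and_grad(self, pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
        diff = pred - target
        loss = float(np.mean(diff ** 2))
        return loss, 2.0 * diff / diff.size


class RMSELoss:
    """Root mean squared error over the whole batch."""

    def value_and_grad(self, pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
        diff = pred - target
        mse = float(np.mean(diff ** 2))
        rmse = np.sqrt(mse)
        if rmse == 0.0:
            return 0.0, np.zeros_like(diff)
        return rmse, diff / (diff.size * rmse)


class SGD:
    def __init__(self, lr: float = 0.01) -> None:
        self.lr = lr

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g in zip(params, grads):
            p -= self.lr * g


class Adam:
    def __init__(self, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Network:
    """A sequential stack of layers with a simple mini-batch fit loop."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [self.forward(x[i:i + batch_size]) for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    def fit(self, x: np.ndarray, y: np.ndarray, loss, optimizer, epochs: int,
            batch_size: int, rng: np.random.Generator,
            shuffle: bool = True) -> list[float]:
        """Train in place; returns the per-epoch mean batch loss."""
        n = x.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        history: list[float] = []
        for epoch in range(epochs):
            order = rng.permutation(n) if shuffle else np.arange(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                pred = self.forward(x[idx])
                l, dpred = loss.value_and_grad(pred, y[idx])
                if not np.isfinite(l):
                    raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
                self.backward(dpred)
                optimizer.step(self.params, self.grads)
                losses.append(l)
            history.append(float(np.mean(losses)))
        return history

    # -- weight (de)serialization ------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w
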