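"""NumPy layers for the patch classifier.

Channels-last layout throughout: activations have shape (batch, H, W, C)
until flattened.  Convolutions use im2col with ``sliding_window_view`` and a
single matmul; 'full' padding grows the spatial edge by kernel - 1, matching
the historical convolution mode of the era's toolkits.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer; stateless layers keep the default empty parameter lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def l2_params(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """2D convolution, stride 1, 'full' (default) or 'same' padding.

    Implemented as k*k shifted GEMMs (shift-and-add) rather than one large
    im2col product: the early layers have few channels, so avoiding the
    k^2-fold column materialization is substantially faster on one CPU.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng, padding: str = "full"):
        if padding not in ("full", "same"):
            raise ValueError(f"unknown padding mode {padding!r}")
        if padding == "same" and k % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel")
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.k, self.c_in, self.c_out, self.padding = k, c_in, c_out, padding

    def out_edge(self, e: int) -> int:
        return e + self.k - 1 if self.padding == "full" else e

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def l2_params(self):
        return [(self.W, self.gW)]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k - 1 if self.padding == "full" else self.k // 2
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))

    def forward(self, x, train=False, rng=None):
        k = self.k
        xp = self._pad(x)
        Ho = xp.shape[1] - k + 1
        Wo = xp.shape[2] - k + 1
        y = np.empty((x.shape[0], Ho, Wo, self.c_out), dtype=self.W.dtype)
        y[...] = self.b
        for di in range(k):
            for dj in range(k):
                seg = xp[:, di : di + Ho, dj : dj + Wo, :]
                y += seg @ self.W[di, dj]
        if train:
            self._cache = (x.shape, xp)
        return y

    def backward(self, dy):
        x_shape, xp = self._cache
        k = self.k
        B, Ho, Wo, _ = dy.shape
        dy2 = dy.reshape(-1, self.c_out)
        self.gb[...] = dy2.sum(axis=0)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                seg = xp[:, di : di + Ho, dj : dj + Wo, :]
                self.gW[di, dj] = seg.reshape(-1, self.c_in).T @ dy2
                dxp[:, di : di + Ho, dj : dj + Wo, :] += dy @ self.W[di, dj].T
        p = k - 1 if self.padding == "full" else k // 2
        H, W = x_shape[1], x_shape[2]
        self._cache = None
        return dxp[:, p : p + H, p : p + W, :]


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped,
    so the output edge is floor(input / 2)."""

    def __init__(self, size: int = 2, stride: int = 2):
        if size != 2 or stride != 2:
            raise ValueError("only 2x2 / stride-2 pooling is supported")

    @staticmethod
    def out_edge(e: int) -> int:
        return e // 2

    def forward(self, x, train=False, rng=None):
        B, H, W, C = x.shape
        Ho, Wo = H // 2, W // 2
        xt = (
            x[:, : 2 * Ho, : 2 * Wo, :]
            .reshape(B, Ho, 2, Wo, 2, C)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(B, Ho, Wo, C, 4)
        )
        idx = xt.argmax(axis=-1)
        y = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, idx)
        return y

    def backward(self, dy):
        x_shape, idx = self._cache
        B, H, W, C = x_shape
        Ho, Wo = H // 2, W // 2
        dxt = np.zeros((B, Ho, Wo, C, 4), dtype=dy.dtype)
        np.put_along_axis(dxt, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros(x_shape, dtype=dy.dtype)
        dx[:, : 2 * Ho, : 2 * Wo, :] = (
            dxt.reshape(B, Ho, Wo, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(B, 2 * Ho, 2 * Wo, C)
        )
        self._cache = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train=False, rng=None):
        if train:
            self._cache = x >= 0
        return np.where(x >= 0, x, self.slope * x)

    def backward(self, dy):
        pos = self._cache
        self._cache = None
        return np.where(pos, dy, self.slope * dy)


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        self._cache = mask
        return x * mask

    def backward(self, dy):
        mask = getattr(self, "_cache", None)
        if mask is None:
            return dy
        self._cache = None
        return dy * mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.n_in, self.n_out = n_in, n_out

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def l2_params(self):
        return [(self.W, self.gW)]

    def forward(self, x, train=False, rng=None):
        if train:
            self._cache = x
        return x @ self.W + self.b

    def backward(self, dy):
        x = self._cache
        self.gW[...] = x.T @ dy
        self.gb[...] = dy.sum(axis=0)
        self._cache = None
        return dy @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Return (mean loss, probabilities, dlogits) for integer class labels."""
    probs = softmax(logits)
    n = len(labels)
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(n), labels] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, probs, dlogits.astype(np.float32)


class Adadelta:
    """Adadelta with a learning-rate multiplier on the computed update."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.001, rho: float = 0.9,
                 eps: float = 1e-6):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.Eg = [np.zeros_like(p) for p in params]
        self.Ed = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        rho, eps = self.rho, self.eps
        for p, g, Eg, Ed in zip(self.params, grads, self.Eg, self.Ed):
            Eg *= rho
            Eg += (1 - rho) * g * g
            delta = -np.sqrt((Ed + eps) / (Eg + eps)) * g
            Ed *= rho
            Ed += (1 - rho) * delta * delta
            p += self.lr * delta
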