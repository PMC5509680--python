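"""The nine-layer convolutional patch classifier.

Layer order: conv, conv, pool, conv, pool, conv, pool, fc, fc(output) —
four convolutional layers (24, 48, 96, 192 filters by default, 360 total),
three max-pooling layers and two fully connected layers.  Convolutions use
stride one with full padding (output edge = input edge + kernel - 1);
pooling uses stride two.  Leaky rectifier nonlinearities everywhere except
the softmax output; dropout 1/3 after each pooling layer and 1/2 after the
hidden fully connected layer.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    Adadelta,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    LeakyReLU,
    MaxPool2,
    softmax,
)


@dataclass(frozen=True)
class NetworkSpec:
    conv_filters: tuple[int, ...] = (24, 48, 96, 192)
    conv_kernels: tuple[int, ...] = (5, 5, 3, 3)
    pool_size: int = 2
    pool_stride: int = 2
    fc_width: int = 256
    dropout_fc: float = 0.5
    dropout_pool: float = 1.0 / 3.0
    leaky_slope: float = 0.01
    n_classes: int = 2
    padding: str = "full"

    def validate(self) -> None:
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ValueError("conv_filters and conv_kernels lengths differ")
        if self.pool_stride != 2 or self.pool_size != 2:
            raise ValueError("only 2x2 stride-2 pooling is supported")

    @property
    def total_filters(self) -> int:
        return int(sum(self.conv_filters))


class IncompatiblePatchEdgeError(ValueError):
    pass


def shape_trace(spec: NetworkSpec, patch_edge: int) -> list[int]:
    """Spatial edge after each conv/pool layer; raises naming the failing
    layer if the patch edge cannot survive the pooling chain."""
    e = patch_edge
    trace = [e]
    for i, (k, _f) in enumerate(zip(spec.conv_kernels, spec.conv_filters)):
        e = e + k - 1 if spec.padding == "full" else e
        trace.append(e)
        if i >= 1:  # pools follow every conv layer except the first
            e = e // spec.pool_stride
            if e < 1:
                raise IncompatiblePatchEdgeError(
                    f"patch edge {patch_edge} collapses to zero at max-pool "
                    f"layer following conv layer {i + 1}"
                )
            trace.append(e)
    return trace


class ConvNet:
    """Maps an (batch, M, M, 3) tile stack to 2-way class probabilities."""

    def __init__(self, spec: NetworkSpec, patch_edge: int, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.patch_edge = int(patch_edge)
        self.trace = shape_trace(spec, self.patch_edge)
        rng = np.random.default_rng(seed)

        layers: list[Layer] = []
        c = 3
        for i, (f, k) in enumerate(zip(spec.conv_filters, spec.conv_kernels)):
            layers.append(Conv2D(c, f, k, rng, spec.padding))
            layers.append(LeakyReLU(spec.leaky_slope))
            if i >= 1:
                layers.append(MaxPool2(spec.pool_size, spec.pool_stride))
                layers.append(Dropout(spec.dropout_pool))
            c = f
        final_edge = self.trace[-1]
        layers.append(Flatten())
        layers.append(Dense(c * final_edge * final_edge, spec.fc_width, rng))
        layers.append(LeakyReLU(spec.leaky_slope))
        layers.append(Dropout(spec.dropout_fc))
        layers.append(Dense(spec.fc_width, spec.n_classes, rng))
        self.layers = layers

    # ------------------------------------------------------------------
    @property
    def total_filters(self) -> int:
        return sum(l.c_out for l in self.layers if isinstance(l, Conv2D))

    @property
    def n_layers(self) -> int:
        """Count per the paper's convention: conv + pool + fc layers."""
        return sum(isinstance(l, (Conv2D, MaxPool2, Dense)) for l in self.layers)

    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]

    def l2_params(self):
        return [pair for l in self.layers for pair in l.l2_params()]

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), values):
            p[...] = v

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Forward pass to logits."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.patch_edge or x.shape[2] != self.patch_edge:
            raise ValueError(
                f"expected {self.patch_edge}x{self.patch_edge} tiles, got {x.shape[1:3]}"
            )
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Deterministic (dropout-free) class probabilities, batched."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        out = np.empty((len(x), self.spec.n_classes), dtype=np.float64)
        for lo in range(0, len(x), batch):
            logits = self.forward(x[lo : lo + batch], train=False)
            out[lo : lo + batch] = softmax(logits)
        return out

    def make_optimizer(self, lr: float, rho: float, eps: float = 1e-6) -> Adadelta:
        return Adadelta(self.params(), lr=lr, rho=rho, eps=eps)


def build_network(spec: NetworkSpec, patch_edge: int, seed: int = 0) -> ConvNet:
    """Build an untrained classifier for M x M x 3 tiles."""
    return ConvNet(spec, patch_edge, seed=seed)
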