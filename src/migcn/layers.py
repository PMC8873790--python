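"""Small trainable layers shared by the extractor and the graph network."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, tensor


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def param(data) -> Tensor:
    t = Tensor(data)
    t.requires_grad = True
    return t


class Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = param(glorot(rng, n_in, n_out))
        self.b = param(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return tensor(x) @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]

    def weights(self):
        return [self.W]


class BatchNorm:
    """Batch normalization over all axes except the last (channel) axis.

    Training uses batch statistics and updates exponential running moments
    (momentum 0.9); inference uses the running statistics.
    """

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = param(np.ones(n_channels))
        self.beta = param(np.zeros(n_channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        x = tensor(x)
        axes = tuple(range(x.ndim - 1))
        if train:
            # reduce over all but the channel axis, keeping dims for broadcast
            mu = x
            for ax in axes:
                mu = mu.mean(axis=ax, keepdims=True)
            centered = x - mu
            var = centered * centered
            for ax in axes:
                var = var.mean(axis=ax, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.reshape(-1)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(-1)
            return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta
        return (
            (x - self.running_mean)
            * (self.running_var + self.eps) ** -0.5
            * self.gamma
            + self.beta
        )

    def parameters(self):
        return [self.gamma, self.beta]


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity in eval mode or at rate 0."""
    if not train or rate == 0.0:
        return tensor(x)
    x = tensor(x)
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)
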