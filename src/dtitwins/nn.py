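"""Minimal NumPy multilayer-perceptron toolkit with manual backpropagation.

Implements exactly the pieces the twin-encoder network needs: linear layers,
batch normalisation with running statistics, ReLU, a sequential container
whose forward pass returns an explicit cache (so one parameter set — the
shared projector — can be applied to several inputs per step and its
gradients summed), the AdamW optimiser with decoupled weight decay, and a
step learning-rate schedule.  All arrays are float64; determinism follows
from seeding a single ``numpy.random.Generator`` for initialisation.
"""

from __future__ import annotations

from typing import Any

import numpy as np


class Linear:
    """Affine layer ``y = x @ W + b`` with uniform fan-in initialisation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_dim)
        self.W = rng.uniform(-bound, bound, size=(in_dim, out_dim))
        self.b = rng.uniform(-bound, bound, size=out_dim)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def set_params(self, values: list[np.ndarray]) -> None:
        self.W, self.b = values

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, Any]:
        return x @ self.W + self.b, x

    def backward(self, grad: np.ndarray, cache: Any
                 ) -> tuple[np.ndarray, list[np.ndarray]]:
        x = cache
        return grad @ self.W.T, [x.T @ grad, grad.sum(axis=0)]


class BatchNorm:
    """1-d batch normalisation.

    Training mode normalises with biased batch statistics and updates the
    running mean/variance (momentum 0.1, unbiased variance, as is
    conventional); inference mode normalises with the running statistics.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    def set_params(self, values: list[np.ndarray]) -> None:
        self.gamma, self.beta = values

    @property
    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def set_buffers(self, values: list[np.ndarray]) -> None:
        self.running_mean, self.running_var = values

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, Any]:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            n = x.shape[0]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean \
                + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var \
                + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean) * inv_std
        return self.gamma * x_hat + self.beta, (x_hat, inv_std, training)

    def backward(self, grad: np.ndarray, cache: Any
                 ) -> tuple[np.ndarray, list[np.ndarray]]:
        x_hat, inv_std, training = cache
        g_gamma = (grad * x_hat).sum(axis=0)
        g_beta = grad.sum(axis=0)
        g_hat = grad * self.gamma
        if training:
            n = grad.shape[0]
            gx = (inv_std / n) * (
                n * g_hat - g_hat.sum(axis=0) - x_hat * (g_hat * x_hat).sum(axis=0)
            )
        else:
            gx = g_hat * inv_std
        return gx, [g_gamma, g_beta]


class ReLU:
    params: list[np.ndarray] = []
    buffers: list[np.ndarray] = []

    def set_params(self, values: list[np.ndarray]) -> None:
        pass

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, Any]:
        mask = x > 0
        return x * mask, mask

    def backward(self, grad: np.ndarray, cache: Any
                 ) -> tuple[np.ndarray, list[np.ndarray]]:
        return grad * cache, []


class Sequential:
    """Layer chain with functional caches so shared modules can be applied
    to several inputs within one optimisation step."""

    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_params(self, values: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            k = len(layer.params)
            layer.set_params(values[i:i + k])
            i += k

    @property
    def buffers(self) -> list[np.ndarray]:
        return [b for layer in self.layers
                for b in getattr(layer, "buffers", [])]

    def set_buffers(self, values: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            bufs = getattr(layer, "buffers", [])
            if bufs:
                layer.set_buffers(values[i:i + len(bufs)])
                i += len(bufs)

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, list]:
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, training)
            caches.append(cache)
        return x, caches

    def backward(self, grad: np.ndarray, caches: list
                 ) -> tuple[np.ndarray, list[np.ndarray]]:
        grads: list[np.ndarray] = []
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            grad, layer_grads = layer.backward(grad, cache)
            grads = layer_grads + grads
        return grad, grads


def mlp_stack(in_dim: int, hidden: int, n_blocks: int, out_dim: int,
              rng: np.random.Generator) -> Sequential:
    """``n_blocks`` repetitions of Linear->BatchNorm->ReLU followed by a
    final linear layer with no activation."""
    layers: list = []
    dim = in_dim
    for _ in range(n_blocks):
        layers += [Linear(dim, hidden, rng), BatchNorm(hidden), ReLU()]
        dim = hidden
    layers.append(Linear(dim, out_dim, rng))
    return Sequential(layers)


class AdamW:
    """Adam with decoupled weight decay (the decay is applied to the
    parameters directly, not folded into the gradient)."""

    def __init__(self, params: list[np.ndarray], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 weight_decay: float = 5e-5, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.weight_decay = weight_decay
        self.eps = eps
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
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * self.weight_decay * p
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class StepLR:
    """Multiply the optimiser learning rate by ``gamma`` every
    ``step_size`` epochs."""

    def __init__(self, optimizer: AdamW, step_size: int, gamma: float):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.step_size = step_size
        self.gamma = gamma

    def set_epoch(self, epoch: int) -> None:
        self.optimizer.lr = self.base_lr * self.gamma ** (epoch // self.step_size)
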