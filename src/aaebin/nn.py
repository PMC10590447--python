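"""Minimal NumPy neural-network layers with explicit backpropagation.

Provides exactly what the adversarial autoencoder needs: dense layers,
batch normalisation, leaky rectifier, an Adam optimiser, and stable
softmax/sigmoid/cross-entropy helpers. Layers cache their forward inputs
and implement ``backward(grad_out) -> grad_in`` accumulating parameter
gradients; an optimiser then steps over an explicit parameter list, so
gradient flow between modules (e.g. encoder through a frozen
discriminator) is controlled by which optimiser is stepped.
"""

from __future__ import annotations

import numpy as np

PROB_EPS = 1e-9  # probability clamp inside every BCE/CE


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.alpha * g)


class BatchNorm(Layer):
    """Batch normalisation with running statistics for evaluation mode."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (x, mean, var, inv_std, xhat)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
            self._cache = None
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, mean, var, inv_std, xhat = self._cache
        n = x.shape[0]
        self.gamma.grad += (g * xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        gxhat = g * self.gamma.value
        # standard batchnorm backward
        gvar = (gxhat * (x - mean)).sum(axis=0) * -0.5 * inv_std**3
        gmean = (
            (gxhat * -inv_std).sum(axis=0)
            + gvar * (-2.0 * (x - mean)).mean(axis=0)
        )
        return gxhat * inv_std + gvar * 2.0 * (x - mean) / n + gmean / n

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    """Adaptive-moment stochastic gradient optimiser."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, g_probs: np.ndarray) -> np.ndarray:
    """Gradient through softmax, given gradient w.r.t. the probabilities."""
    dot = (g_probs * probs).sum(axis=-1, keepdims=True)
    return probs * (g_probs - dot)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce(p: np.ndarray, label: float) -> float:
    """Mean binary cross-entropy of probabilities against a constant label,
    with probabilities clamped to [PROB_EPS, 1 - PROB_EPS]."""
    p = np.clip(np.asarray(p, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
    if label == 1:
        return float(-np.log(p).mean())
    if label == 0:
        return float(-np.log1p(-p).mean())
    return float((-label * np.log(p) - (1 - label) * np.log1p(-p)).mean())


def cross_entropy(p_true: np.ndarray, p_pred: np.ndarray) -> float:
    """Mean over rows of -sum_s p_true * log(p_pred), clamped."""
    p_pred = np.clip(p_pred, PROB_EPS, None)
    return float(-(p_true * np.log(p_pred)).sum(axis=-1).mean())


def gumbel_softmax(
    logits: np.ndarray, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Relaxed one-hot categorical sample at temperature ``tau``."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    g = rng.gumbel(size=logits.shape)
    return softmax((logits + g) / tau, axis=-1)
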