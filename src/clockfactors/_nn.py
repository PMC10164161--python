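"""Minimal dense neural-network core: layers, explicit backprop, Adam.

Everything here is plain numpy. Shapes follow the (batch, features)
convention; every layer caches what its backward pass needs, so a
forward must precede the matching backward.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Dense", "MLP", "Adam", "relu", "sigmoid"]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable in both tails
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Dense:
    """Affine layer y = x W + b with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.W = Param(w)
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.T @ grad_out
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.W.value.T

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]


class MLP:
    """Stack of Dense layers with ReLU between them (linear final layer)."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 zero_init_last: bool = False):
        self.layers = []
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = i == len(sizes) - 2
            self.layers.append(Dense(a, b, rng, zero_init=zero_init_last and last))
        self._acts: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._acts = []
        h = x
        for i, layer in enumerate(self.layers):
            h = layer.forward(h)
            if i < len(self.layers) - 1:
                h = relu(h)
                self._acts.append(h)
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                g = g * (self._acts[i] > 0)
            g = self.layers[i].backward(g)
        return g

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]


class Adam:
    """Adam optimizer over a list of Params."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
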