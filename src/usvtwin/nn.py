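"""Minimal dense neural-network layers with Adam, used by the adversarial
twin generator.

Only what tabular generation at ~100-row scale needs: fully connected
layers, ReLU, explicit backprop, and logistic losses.  Everything is plain
numpy and deterministic given the RNG handed in by the caller.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "bce_with_logits", "bce_grad", "sigmoid", "softmax"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy, numerically stable."""
    return float(np.mean(np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))))


def bce_grad(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d logits."""
    return (sigmoid(logits) - targets) / logits.shape[0]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        # Adam state
        self.mW = np.zeros_like(self.W)
        self.vW = np.zeros_like(self.W)
        self.mb = np.zeros_like(self.b)
        self.vb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ dy
        self.gb += dy.sum(axis=0)
        return dy @ self.W.T


class MLP:
    """Fully connected net with ReLU hidden layers and a linear output."""

    def __init__(
        self,
        n_in: int,
        hidden: tuple[int, ...],
        n_out: int,
        rng: np.random.Generator,
    ):
        dims = [n_in, *hidden, n_out]
        self.layers = [_Dense(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self._t = 0
        self._acts: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._acts = []
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i < len(self.layers) - 1:
                x = np.maximum(x, 0.0)
                self._acts.append(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients; return gradient w.r.t. the input."""
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                dy = dy * (self._acts[i] > 0)
            dy = self.layers[i].backward(dy)
        return dy

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.gW[:] = 0.0
            layer.gb[:] = 0.0

    def step(self, lr: float, beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8) -> None:
        """Adam update from accumulated gradients, then reset them."""
        self._t += 1
        b1c = 1.0 - beta1**self._t
        b2c = 1.0 - beta2**self._t
        for layer in self.layers:
            for p, g, m, v in (
                (layer.W, layer.gW, layer.mW, layer.vW),
                (layer.b, layer.gb, layer.mb, layer.vb),
            ):
                m *= beta1
                m += (1.0 - beta1) * g
                v *= beta2
                v += (1.0 - beta2) * g * g
                p -= lr * (m / b1c) / (np.sqrt(v / b2c) + eps)
        self.zero_grads()
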