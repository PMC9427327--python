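"""Minimal dense neural-network machinery: MLPs with manual backprop and Adam.

All state is explicit numpy arrays; forward passes return a cache that the
matching backward pass consumes, so gradient flow is fully under the caller's
control (needed for the adversarial step, where the discriminator's parameters
are held fixed while gradients flow to its inputs).
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "leaky_relu", "leaky_relu_grad"]


def leaky_relu(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def leaky_relu_grad(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


class MLP:
    """Fully connected net with leaky-rectifier hidden activations, linear output.

    Parameters are a flat list [W1, b1, W2, b2, ...] with W of shape
    (fan_in, fan_out). Initialization is He-style scaled normal from the
    supplied generator, so construction is reproducible by seed.
    """

    def __init__(self, dims: tuple[int, ...], rng: np.random.Generator,
                 slope: float = 0.2):
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output widths")
        self.dims = tuple(int(d) for d in dims)
        self.slope = float(slope)
        self.params: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.dims[:-1], self.dims[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.params.append(rng.standard_normal((fan_in, fan_out)) * scale)
            self.params.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.dims) - 1

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        """Return (output, cache); cache holds pre-activations for backward."""
        if x.ndim != 2 or x.shape[1] != self.dims[0]:
            raise ValueError(
                f"expected input of width {self.dims[0]}, got shape {x.shape}")
        cache = []
        a = x
        for layer in range(self.n_layers):
            W, b = self.params[2 * layer], self.params[2 * layer + 1]
            pre = a @ W + b
            cache.append((a, pre))
            a = pre if layer == self.n_layers - 1 else leaky_relu(pre, self.slope)
        return a, cache

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, cache: list, grad_out: np.ndarray
                 ) -> tuple[list[np.ndarray], np.ndarray]:
        """Backprop grad_out (d loss / d output) through the cached forward.

        Returns (grads, grad_in) where grads mirrors ``params``.
        """
        grads: list[np.ndarray | None] = [None] * len(self.params)
        g = grad_out
        for layer in range(self.n_layers - 1, -1, -1):
            a_in, pre = cache[layer]
            if layer != self.n_layers - 1:
                g = g * leaky_relu_grad(pre, self.slope)
            W = self.params[2 * layer]
            grads[2 * layer] = a_in.T @ g
            grads[2 * layer + 1] = g.sum(axis=0)
            g = g @ W.T
        return grads, g  # type: ignore[return-value]


class Adam:
    """Adam optimizer over a flat list of parameter arrays, updated in place."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
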