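"""Small numeric helpers shared by the network modules."""

from __future__ import annotations

import numpy as np


def leaky_relu(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def leaky_relu_grad(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    """Derivative of LeakyReLU wrt its pre-activation (1 at x == 0)."""
    return np.where(x >= 0, 1.0, slope)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)
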