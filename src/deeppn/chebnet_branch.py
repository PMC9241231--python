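"""Spectral graph-convolution branch.

Two Chebyshev convolution layers over the sequence-position graph, each
followed by LeakyReLU, preceded by a learnable per-position linear
embedding of the 4 one-hot channels and followed by a row-major flatten.
A K-term Chebyshev filter aggregates information from nodes up to K-1
hops away, so with the default path graph each layer has a receptive
field of +-(K-1) positions.

The filter of order K with coefficients theta (shape K x C_in x C_out) is

    out[:, c_out] = sum_k T_k(Ltilde) @ signal @ theta[k, :, c_out],

i.e. a polynomial in the rescaled Laplacian applied channel-wise — the
standard eigendecomposition-free form of a spectral graph filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import leaky_relu
from .seq_encoding import OneHotMatrix
from .seq_graph import ScaledLaplacian, chebyshev_basis


@dataclass(frozen=True)
class ChebLayerParams:
    """Chebyshev filter coefficients theta, shape (K, in_channels, out_channels)."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.theta, dtype=float)
        if t.ndim != 3:
            raise ValueError(f"theta must be (K, in, out), got shape {t.shape}")
        if not np.all(np.isfinite(t)):
            raise ValueError("theta contains non-finite coefficients")
        object.__setattr__(self, "theta", t)

    @property
    def K(self) -> int:
        return self.theta.shape[0]

    @property
    def in_channels(self) -> int:
        return self.theta.shape[1]

    @property
    def out_channels(self) -> int:
        return self.theta.shape[2]


@dataclass(frozen=True)
class BranchFeatureVector:
    """Flattened output of one branch, tagged with its origin."""

    values: np.ndarray
    origin: str  # "chebnet" or "cnn"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("branch feature vector is empty")
        object.__setattr__(self, "values", v)
        if self.origin not in ("chebnet", "cnn"):
            raise ValueError(f"unknown branch origin {self.origin!r}")

    def __len__(self) -> int:
        return self.values.size


def cheb_conv(signal: np.ndarray, ltilde: ScaledLaplacian, params: ChebLayerParams) -> np.ndarray:
    """Chebyshev spectral convolution of an L x C_in node signal.

    Linear both in the signal and in theta; term k touches the k-hop
    neighbourhood of each node.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = signal[:, None]
    if signal.shape[0] != ltilde.n_nodes:
        raise ValueError(
            f"signal has {signal.shape[0]} rows but graph has {ltilde.n_nodes} nodes"
        )
    if signal.shape[1] != params.in_channels:
        raise ValueError(
            f"signal has {signal.shape[1]} channels but params expect {params.in_channels}"
        )
    basis = chebyshev_basis(ltilde, params.K)
    # (K,L,L) x (L,Cin) -> (K,L,Cin), then contract K and Cin with theta
    terms = np.einsum("kij,jc->kic", basis, signal)
    return np.einsum("kic,kcd->id", terms, params.theta)


@dataclass(frozen=True)
class PreprocessParams:
    """Per-position linear embedding of the one-hot channels: X W + b."""

    weight: np.ndarray  # (4, C)
    bias: np.ndarray  # (C,)

    @classmethod
    def identity(cls, channels: int = 4) -> "PreprocessParams":
        """Identity-extension: first 4 output channels reproduce X."""
        w = np.zeros((4, channels))
        w[:, :4] = np.eye(4)[:, : min(4, channels)]
        return cls(weight=w, bias=np.zeros(channels))


def preprocess(X: OneHotMatrix | np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Embed the 4 one-hot channels into C channels, position-locally."""
    values = X.values if isinstance(X, OneHotMatrix) else np.asarray(X, dtype=float)
    if values.shape[-1] != params.weight.shape[0]:
        raise ValueError(
            f"input has {values.shape[-1]} channels, projection expects {params.weight.shape[0]}"
        )
    return values @ params.weight + params.bias


def chebnet_forward(
    X: OneHotMatrix | np.ndarray,
    ltilde: ScaledLaplacian,
    pre: PreprocessParams,
    layer1: ChebLayerParams,
    layer2: ChebLayerParams,
    slope: float = 0.01,
) -> BranchFeatureVector:
    """Full branch: embed, two Chebyshev convolutions with LeakyReLU, flatten.

    The flatten is row-major over (position, channel) and fixed, so the
    dense head sees a stable feature layout.
    """
    h = preprocess(X, pre)
    h = leaky_relu(cheb_conv(h, ltilde, layer1), slope)
    h = leaky_relu(cheb_conv(h, ltilde, layer2), slope)
    return BranchFeatureVector(values=h.reshape(-1), origin="chebnet")
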