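"""Convolutional motif-scanning branch.

Two 1-D convolution layers slide learnable filters over the one-hot
sequence (cross-correlation semantics, stride 1, no pooling), each
followed by LeakyReLU, then a row-major flatten.  The first layer's
filters act as soft position-weight-matrix scanners; the second layer
combines their local responses.  Default widths follow the classic
motif-scanner setup: 16 then 32 filters sharing one kernel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import leaky_relu
from .chebnet_branch import BranchFeatureVector
from .seq_encoding import OneHotMatrix


@dataclass(frozen=True)
class ConvLayerParams:
    """Sliding-window weights (filter_count, kernel_size, in_channels) and bias."""

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        b = np.asarray(self.bias, dtype=float)
        if w.ndim != 3:
            raise ValueError(f"weights must be (filters, kernel, in_channels), got {w.shape}")
        if w.shape[1] < 1:
            raise ValueError("kernel_size must be >= 1")
        if b.shape != (w.shape[0],):
            raise ValueError(f"bias shape {b.shape} does not match {w.shape[0]} filters")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
            raise ValueError("non-finite convolution parameters")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "bias", b)

    @property
    def filter_count(self) -> int:
        return self.weights.shape[0]

    @property
    def kernel_size(self) -> int:
        return self.weights.shape[1]

    @property
    def in_channels(self) -> int:
        return self.weights.shape[2]


def conv1d(signal: np.ndarray, params: ConvLayerParams, padding_mode: str = "valid") -> np.ndarray:
    """1-D cross-correlation of an L x C_in signal with the filter bank.

    "valid" yields L - kernel + 1 output positions; "same" zero-pads the
    signal so the output keeps length L.  No kernel flip is applied.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2:
        raise ValueError(f"signal must be L x C, got shape {signal.shape}")
    if signal.shape[1] != params.in_channels:
        raise ValueError(
            f"signal has {signal.shape[1]} channels but filters expect {params.in_channels}"
        )
    k = params.kernel_size
    if padding_mode == "same":
        left = (k - 1) // 2
        signal = np.pad(signal, ((left, k - 1 - left), (0, 0)))
    elif padding_mode != "valid":
        raise ValueError(f"unknown padding_mode {padding_mode!r}")
    if k > signal.shape[0]:
        raise ValueError(
            f"kernel size {k} exceeds signal length {signal.shape[0]} in 'valid' mode"
        )
    # windows: (L', kernel, C_in)
    windows = np.lib.stride_tricks.sliding_window_view(signal, k, axis=0)
    windows = windows.transpose(0, 2, 1)
    return np.einsum("lkc,fkc->lf", windows, params.weights) + params.bias


def cnn_forward(
    X: OneHotMatrix | np.ndarray,
    layer1: ConvLayerParams,
    layer2: ConvLayerParams,
    slope: float = 0.01,
    padding_mode: str = "valid",
) -> BranchFeatureVector:
    """Full branch: two convolutions with LeakyReLU, then row-major flatten."""
    if layer1.kernel_size != layer2.kernel_size:
        raise ValueError("both convolution layers must share one kernel size")
    values = X.values if isinstance(X, OneHotMatrix) else np.asarray(X, dtype=float)
    h = leaky_relu(conv1d(values, layer1, padding_mode), slope)
    h = leaky_relu(conv1d(h, layer2, padding_mode), slope)
    return BranchFeatureVector(values=h.reshape(-1), origin="cnn")
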