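"""Graph structure over sequence positions for the spectral branch.

A linear RNA sequence is modelled as an undirected path graph over its L
positions, optionally widened to a neighbour radius ``w`` (node i connects
to all nodes within distance w along the backbone).  The spectral filters
act on the symmetric normalized Laplacian rescaled to put its spectrum in
[-1, 1], where Chebyshev polynomials are well behaved:

    L = I - D^{-1/2} A D^{-1/2},    Ltilde = 2 L / lambda_max - I.

One graph is shared by every sequence window of the same length — only the
node features differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SequenceGraph:
    """Path-with-window graph over sequence positions.

    adjacency[i, j] = 1 iff 0 < |i - j| <= window.
    """

    n_nodes: int
    adjacency: np.ndarray
    window: int


@dataclass(frozen=True)
class ScaledLaplacian:
    """Rescaled symmetric normalized Laplacian with spectrum in [-1, 1]."""

    matrix: np.ndarray
    lambda_max: float

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def build_sequence_graph(length: int, window: int = 1) -> SequenceGraph:
    """Build the position graph for a sequence of ``length`` nodes."""
    if length < 2:
        raise ValueError("graph needs at least 2 nodes")
    if window < 1 or window >= length:
        raise ValueError(f"window must satisfy 1 <= window < length, got {window}")
    idx = np.arange(length)
    dist = np.abs(idx[:, None] - idx[None, :])
    adjacency = ((dist > 0) & (dist <= window)).astype(float)
    return SequenceGraph(n_nodes=length, adjacency=adjacency, window=window)


def scaled_laplacian(graph: SequenceGraph, lambda_max_mode: str = "exact") -> ScaledLaplacian:
    """Compute Ltilde = 2 L / lambda_max - I for the graph.

    ``lambda_max_mode`` is either "exact" (top eigenvalue of L, computed
    once per window length) or "approx2" (the common shortcut lambda_max=2,
    an upper bound for any normalized Laplacian).
    """
    degrees = graph.adjacency.sum(axis=1)
    if np.any(degrees == 0):
        raise ValueError("graph has an isolated node; Laplacian normalisation undefined")
    d_inv_sqrt = 1.0 / np.sqrt(degrees)
    n = graph.n_nodes
    lap = np.eye(n) - (d_inv_sqrt[:, None] * graph.adjacency * d_inv_sqrt[None, :])
    lap = (lap + lap.T) / 2.0  # enforce exact symmetry
    if lambda_max_mode == "exact":
        lambda_max = float(np.linalg.eigvalsh(lap)[-1])
    elif lambda_max_mode == "approx2":
        lambda_max = 2.0
    else:
        raise ValueError(f"unknown lambda_max_mode {lambda_max_mode!r}")
    ltilde = 2.0 * lap / lambda_max - np.eye(n)
    return ScaledLaplacian(matrix=ltilde, lambda_max=lambda_max)


def chebyshev_apply(ltilde: ScaledLaplacian, signal: np.ndarray, K: int) -> list[np.ndarray]:
    """Apply the first K Chebyshev polynomials of Ltilde to a node signal.

    Returns [T_0(Lt) s, ..., T_{K-1}(Lt) s] via the three-term recursion
    T_k = 2 Lt T_{k-1} - T_{k-2} with T_0 = I and T_1 = Lt, avoiding any
    eigendecomposition.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = signal[:, None]
    if signal.shape[0] != ltilde.n_nodes:
        raise ValueError(
            f"signal has {signal.shape[0]} rows but graph has {ltilde.n_nodes} nodes"
        )
    terms = [signal]
    if K > 1:
        terms.append(ltilde.matrix @ signal)
    for _ in range(2, K):
        terms.append(2.0 * ltilde.matrix @ terms[-1] - terms[-2])
    return terms


def chebyshev_basis(ltilde: ScaledLaplacian, K: int) -> np.ndarray:
    """Dense polynomial operators T_k(Ltilde), stacked as a (K, L, L) array.

    For the fixed, modest graphs used here (one per window length)
    materialising the K operators once is cheaper than re-running the
    recursion on every signal, and makes both the convolution and its
    gradient single matrix products.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = ltilde.n_nodes
    basis = np.empty((K, n, n))
    basis[0] = np.eye(n)
    if K > 1:
        basis[1] = ltilde.matrix
    for k in range(2, K):
        basis[k] = 2.0 * ltilde.matrix @ basis[k - 1] - basis[k - 2]
    return basis
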