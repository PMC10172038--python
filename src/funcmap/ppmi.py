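"""Positive pointwise mutual information representation of a network.

Instead of the bare adjacency matrix, the network is represented by the
closed-form random-walk co-occurrence matrix popularised by DeepWalk/NetMF:
with adjacency A, degree matrix D, transition matrix P = D^-1 A, graph
volume vol = sum of degrees, context window T and negative-sampling
parameter b,

    M = vol / (b * T) * (sum_{r=1..T} P^r) D^-1
    PPMI = max(log M, 0)        (entries with M = 0 stay 0)

Each entry of M measures how often two nodes co-occur within T steps of a
random walk, normalised so that log M is a pointwise mutual information;
clamping at zero keeps only positively associated node pairs. The result is
a symmetric non-negative dense matrix aligned to the network's node order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import DataError, Network

__all__ = ["PPMIMatrix", "ppmi_matrix"]


@dataclass(frozen=True)
class PPMIMatrix:
    """Symmetric non-negative PPMI matrix with its node order and parameters."""

    values: np.ndarray
    node_order: tuple[str, ...]
    window: int
    negatives: int

    def __post_init__(self) -> None:
        n = len(self.node_order)
        if self.values.shape != (n, n):
            raise DataError("PPMI matrix shape does not match node order")
        if np.any(self.values < 0):
            raise DataError("PPMI matrix must be non-negative")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise DataError("PPMI matrix must be symmetric")


def ppmi_matrix(network: Network, window: int = 10, negatives: int = 1) -> PPMIMatrix:
    """Compute the closed-form PPMI matrix of an undirected network.

    Parameters
    ----------
    network
        Undirected simple graph; every node must have degree >= 1.
    window
        Random-walk context window T (number of diffusion steps summed).
        Default 10.
    negatives
        Negative-sampling constant b of the underlying word2vec analogy.
        Default 1.
    """
    if window < 1:
        raise DataError("window must be >= 1")
    if negatives < 1:
        raise DataError("negatives must be >= 1")
    if network.n_nodes < 2:
        raise DataError("network must have at least 2 nodes")
    a = network.adjacency()
    deg = a.sum(axis=1)
    if np.any(deg == 0):
        isolated = [network.nodes[i] for i in np.flatnonzero(deg == 0)]
        raise DataError(f"isolated nodes (degree 0): {isolated[:5]}")
    vol = deg.sum()
    p = a / deg[:, None]
    acc = np.zeros_like(a)
    power = np.eye(len(deg))
    for _ in range(window):
        power = power @ p
        acc += power
    m = (vol / (negatives * window)) * acc / deg[None, :]
    with np.errstate(divide="ignore"):
        out = np.where(m > 0, np.log(np.where(m > 0, m, 1.0)), 0.0)
    out = np.maximum(out, 0.0)
    out = (out + out.T) / 2.0  # kill float asymmetry of the matrix products
    return PPMIMatrix(values=out, node_order=network.nodes, window=window, negatives=negatives)
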