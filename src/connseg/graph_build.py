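"""From ROI time series to Fisher-z matrices and multi-threshold binary graphs.

Pairwise Pearson correlations between ROI signals are Fisher z-transformed
(atanh) into a symmetric connectivity matrix, which is then binarized by
*proportional thresholding*: at proportion ``p`` exactly
``round(p * n(n-1)/2)`` of the strongest (largest signed z) node pairs
become edges of an undirected simple graph.  A scan is analysed at several
proportions at once because there is no agreed-upon single cutoff; the
default set keeps the top 5, 10, 20, 25, 30 and 40% of connections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

#: Default edge-retention proportions.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.05, 0.10, 0.20, 0.25, 0.30, 0.40)

#: Cap on |z| so perfectly correlated signals stay finite.
FISHER_Z_CAP = math.atanh(1 - 1e-7)


def fisher_z_connectivity(ts: np.ndarray) -> np.ndarray:
    """Fisher-z connectivity matrix of an ROI-by-time signal matrix.

    Off-diagonal entry (i, j) is ``atanh(r_ij)`` of the Pearson correlation
    between rows i and j, capped at ``±atanh(1 - 1e-7)``; the diagonal is
    stored as 0 and ignored by all consumers.

    Raises
    ------
    ValueError
        If fewer than 3 time points are supplied, or any ROI signal is
        constant (its correlations are undefined); the error names the ROI.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D ROI-by-time array")
    n, T = ts.shape
    if T < 3:
        raise ValueError(f"need at least 3 time points, got {T}")
    sd = ts.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"constant signal for ROI(s) {flat.tolist()}: correlation undefined"
        )
    r = np.corrcoef(ts)
    r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    z = np.arctanh(r)
    z = np.clip(z, -FISHER_Z_CAP, FISHER_Z_CAP)
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return z


def edge_count(n_nodes: int, p: float) -> int:
    """Edges retained at proportion p: round-half-away-from-zero of
    ``p * n(n-1)/2``."""
    x = p * n_nodes * (n_nodes - 1) / 2
    return int(math.floor(x + 0.5))


def proportional_threshold(
    matrix: np.ndarray, p: float, ranking: str = "signed"
) -> np.ndarray:
    """Binarize a connectivity matrix, keeping the top-``p`` fraction of pairs.

    Ranks node pairs by signed z-value by default (a strongly negative
    correlation is never a "strongest connection"); ``ranking="absolute"``
    ranks by |z| instead.  Ties are broken by ascending (i, j) lexicographic
    node order so results are bit-reproducible.  Returns the boolean
    adjacency matrix of an undirected simple graph.
    """
    if not (0 < p <= 1):
        raise ValueError(f"threshold proportion must be in (0, 1], got {p}")
    if ranking not in ("signed", "absolute"):
        raise ValueError(f"ranking must be 'signed' or 'absolute', got {ranking!r}")
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = matrix[iu, ju]
    if ranking == "absolute":
        vals = np.abs(vals)
    m = edge_count(n, p)
    # lexsort keys: last key is primary -> sort by -value, then i, then j
    order = np.lexsort((ju, iu, -vals))[:m]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[order], ju[order]] = True
    return adj | adj.T


@dataclass(frozen=True)
class BinaryGraphSet:
    """Undirected binary graphs obtained from one matrix at several thresholds."""

    thresholds: tuple[float, ...]
    adjacency: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.adjacency):
            raise ValueError("thresholds and adjacency lists differ in length")

    @property
    def n_nodes(self) -> int:
        return self.adjacency[0].shape[0]

    def __len__(self) -> int:
        return len(self.thresholds)

    def to_networkx(self, index: int, labels=None) -> nx.Graph:
        """Export one threshold's graph as a networkx Graph (optionally
        relabelled)."""
        g = nx.from_numpy_array(self.adjacency[index].astype(int))
        if labels is not None:
            g = nx.relabel_nodes(g, dict(enumerate(labels)))
        return g


def multi_threshold_graphs(
    matrix: np.ndarray, thresholds=DEFAULT_THRESHOLDS, ranking: str = "signed"
) -> BinaryGraphSet:
    """Threshold one matrix at each proportion, preserving order."""
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    adj = tuple(proportional_threshold(matrix, p, ranking) for p in thresholds)
    return BinaryGraphSet(thresholds, adj)
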