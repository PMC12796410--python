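"""Density-thresholded binary graphs and the five network metrics.

Four metrics (global efficiency, local efficiency, clustering coefficient,
degree assortativity) are computed on the binary graph obtained by keeping
the top ``density`` fraction of wPLI weights; node strength is computed on
the weighted matrix *before* thresholding.  All graph algorithms here are
self-contained (BFS shortest paths, A^3 triangle counts, degree-degree
Pearson correlation) so they can be validated against an independent
reference implementation.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "BinaryGraph",
    "MetricsRow",
    "binarize_density",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "node_strength",
    "assortativity",
    "compute_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "Global_Efficiency",
    "Local_Efficiency",
    "Clustering_Coefficient",
    "Node_Strength",
    "Assortativity",
)


@dataclass
class BinaryGraph:
    """Symmetric 0/1 adjacency with zero diagonal and fixed edge count."""

    adjacency: np.ndarray
    density: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass
class MetricsRow:
    """The five graph metrics for one participant x condition x band."""

    participant_id: str
    condition: str
    band: str
    global_efficiency: float
    local_efficiency: float
    clustering_coefficient: float
    node_strength: float
    assortativity: float  # NaN when undefined (degree-regular graph)


def binarize_density(w: ConnectivityMatrix, density: float = 0.2) -> BinaryGraph:
    """Keep the k = floor(density * n(n-1)/2) strongest weights as edges.

    Ties at the cutoff are broken by ascending (i, j) index order, so the
    edge count is exactly k regardless of ties.  An all-zero matrix has no
    rankable edges and is an error.
    """
    if not (0.0 < density < 1.0):
        raise ValueError(f"density must be in (0, 1), got {density}")
    n = w.n_channels
    if n < 2:
        raise ValueError("need at least 2 channels")
    weights = w.weights
    if not np.any(weights > 0):
        raise ValueError("all-zero connectivity matrix: no rankable edges")
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, -weights[iu, ju]))
    k = math.floor(density * n * (n - 1) / 2)
    adj = np.zeros((n, n), dtype=np.int8)
    keep = order[:k]
    adj[iu[keep], ju[keep]] = 1
    adj[ju[keep], iu[keep]] = 1
    return BinaryGraph(adjacency=adj, density=density)


def _bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in np.nonzero(adj[u])[0]:
            if not np.isfinite(dist[v]):
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _efficiency_from_adj(adj: np.ndarray) -> float:
    """Mean inverse BFS shortest-path length; disconnected pairs count 0."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for s in range(n):
        d = _bfs_distances(adj, s)
        finite = np.isfinite(d) & (d > 0)
        total += float((1.0 / d[finite]).sum())
    return total / (n * (n - 1))


def global_efficiency(g: BinaryGraph) -> float:
    """Average inverse shortest path length over all ordered node pairs."""
    return _efficiency_from_adj(g.adjacency)


def local_efficiency(g: BinaryGraph) -> float:
    """Mean over nodes of the efficiency of the neighbor-induced subgraph.

    Nodes with fewer than two neighbors contribute 0.
    """
    adj = g.adjacency
    n = g.n_nodes
    acc = 0.0
    for u in range(n):
        nbrs = np.nonzero(adj[u])[0]
        if nbrs.size >= 2:
            acc += _efficiency_from_adj(adj[np.ix_(nbrs, nbrs)])
    return acc / n


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean over nodes of 2 t_i / (k_i (k_i - 1)); degree < 2 contributes 0."""
    adj = g.adjacency.astype(np.int64)
    deg = adj.sum(axis=1)
    triangles = np.diag(adj @ adj @ adj) / 2.0
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / np.maximum(denom, 1), 0.0)
    return float(c.mean())


def node_strength(w: ConnectivityMatrix) -> float:
    """Mean over nodes of the per-node sum of pre-threshold edge weights."""
    return float(w.weights.sum(axis=1).mean())


def assortativity(g: BinaryGraph) -> float:
    """Degree assortativity: Pearson r of endpoint degrees over directed edges.

    Each undirected edge is counted in both orientations.  Returns NaN
    (the undefined flag) when the endpoint degrees have zero variance, as in
    any degree-regular graph.  An edgeless graph is an error.
    """
    if g.n_edges == 0:
        raise ValueError("assortativity undefined for an edgeless graph")
    deg = g.degrees()
    iu, ju = np.nonzero(np.triu(g.adjacency, k=1))
    x = np.concatenate([deg[iu], deg[ju]]).astype(float)
    y = np.concatenate([deg[ju], deg[iu]]).astype(float)
    if np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def compute_metrics(
    w: ConnectivityMatrix, density: float = 0.2
) -> MetricsRow:
    """Binarize at ``density`` and return all five metrics as one row."""
    g = binarize_density(w, density=density)
    return MetricsRow(
        participant_id=w.participant_id,
        condition=w.condition,
        band=w.band.name,
        global_efficiency=global_efficiency(g),
        local_efficiency=local_efficiency(g),
        clustering_coefficient=clustering_coefficient(g),
        node_strength=node_strength(w),
        assortativity=assortativity(g),
    )
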