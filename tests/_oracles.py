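"""Independent reference implementations used only as test oracles.

Everything here is deliberately written by a different route than the
package code: networkx for graph metrics, a naive explicit-exponential DFT
for the wPLI cross-spectra, exhaustive enumeration for the rank tests, and
a brute-force minimum-variance merge search for Ward clustering.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx
import numpy as np


# ---------------------------------------------------------------- graphs
def nx_graph(adj: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(adj.shape[0]))
    i, j = np.nonzero(np.triu(adj, k=1))
    g.add_edges_from(zip(i.tolist(), j.tolist()))
    return g


def global_efficiency_nx(adj: np.ndarray) -> float:
    return nx.global_efficiency(nx_graph(adj))


def local_efficiency_nx(adj: np.ndarray) -> float:
    return nx.local_efficiency(nx_graph(adj))


def clustering_nx(adj: np.ndarray) -> float:
    return nx.average_clustering(nx_graph(adj))


def assortativity_nx(adj: np.ndarray) -> float:
    g = nx_graph(adj)
    deg = dict(g.degree())
    x, y = [], []
    for u, v in g.edges():
        x += [deg[u], deg[v]]
        y += [deg[v], deg[u]]
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.var(x) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def node_strength_direct(weights: np.ndarray) -> float:
    n = weights.shape[0]
    return float(sum(weights[i].sum() for i in range(n)) / n)


# ------------------------------------------------------------------ wPLI
def wpli_direct_dft(epochs: np.ndarray, rate_hz: float, low: float, high: float):
    """wPLI via an explicit O(N^2) DFT and per-pair loops."""
    n_ep, n_ch, L = epochs.shape
    t = np.arange(L)
    freqs = np.array([k * rate_hz / L for k in range(L // 2 + 1)])
    bins = [k for k, f in enumerate(freqs) if low <= f <= high]
    taper = np.hanning(L)
    # explicit DFT matrix, built from exponentials (not np.fft)
    Z = np.zeros((n_ep, n_ch, len(bins)), dtype=complex)
    for e in range(n_ep):
        for c in range(n_ch):
            xs = epochs[e, c] * taper
            for bi, k in enumerate(bins):
                Z[e, c, bi] = np.sum(xs * np.exp(-2j * np.pi * k * t / L))
    w = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(n_ch):
            if i == j:
                continue
            num = 0.0
            den = 0.0
            for e in range(n_ep):
                for bi in range(len(bins)):
                    im = (Z[e, i, bi] * np.conj(Z[e, j, bi])).imag
                    num += im
                    den += abs(im)
            w[i, j] = abs(num) / den if den > 0 else 0.0
    return w


# ------------------------------------------------------------ rank tests
def mannwhitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney by enumerating all group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)

    def u1_of(idx_x):
        xs = pooled[list(idx_x)]
        ys = pooled[[i for i in range(n) if i not in idx_x]]
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    us = [u1_of(c) for c in itertools.combinations(range(n), n1)]
    center = n1 * (n - n1) / 2.0
    dev = abs(u_obs - center) - 1e-12
    p = sum(abs(u - center) >= dev for u in us) / len(us)
    return u_obs, p


def wilcoxon_enumeration(pre, post):
    """Exact two-sided signed-rank p by enumerating all sign flips."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    center = n * (n + 1) / 4.0
    dev = abs(w_obs - center) - 1e-12
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - center) >= dev:
            count += 1
    return w_obs, count / 2**n


def hypergeom_pmf(a, row1, col1, n):
    """P(top-left cell = a) with fixed margins."""
    return comb(col1, a) * comb(n - col1, row1 - a) / comb(n, row1)


def fisher_enumeration(table):
    """Two-sided Fisher p by probability ordering over the support."""
    t = np.asarray(table, dtype=int)
    a = int(t[0, 0])
    row1 = int(t[0].sum())
    col1 = int(t[:, 0].sum())
    n = int(t.sum())
    p_obs = hypergeom_pmf(a, row1, col1, n)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom_pmf(k, row1, col1, n)
        if pk <= p_obs * (1 + 1e-7):  # probability-ordering rule with slack
            total += pk
    return min(total, 1.0)


# ------------------------------------------------------------------ Ward
def ward_merge_sequence(points: np.ndarray):
    """Greedy exhaustive-search Ward: at each step evaluate every merge's
    within-cluster variance increase and take the minimum.  Returns the list
    of partitions (as sets of frozensets of point indices) after each merge."""
    clusters = [frozenset([i]) for i in range(len(points))]
    partitions = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a = points[list(clusters[i])]
            b = points[list(clusters[j])]
            na, nb = len(a), len(b)
            delta = (
                na * nb / (na + nb)
                * float(((a.mean(axis=0) - b.mean(axis=0)) ** 2).sum())
            )
            if best is None or delta < best[0]:
                best = (delta, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        partitions.append(set(clusters))
    return partitions


# ------------------------------------------------------- KMO (3 features)
def kmo3_by_hand(data: np.ndarray) -> float:
    """Overall KMO for exactly 3 features via the adjugate-matrix inverse."""
    assert data.shape[1] == 3
    R = np.corrcoef(data, rowvar=False)
    det = (
        R[0, 0] * (R[1, 1] * R[2, 2] - R[1, 2] * R[2, 1])
        - R[0, 1] * (R[1, 0] * R[2, 2] - R[1, 2] * R[2, 0])
        + R[0, 2] * (R[1, 0] * R[2, 1] - R[1, 1] * R[2, 0])
    )
    cof = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            minor = np.delete(np.delete(R, i, axis=0), j, axis=1)
            cof[i, j] = (-1) ** (i + j) * (
                minor[0, 0] * minor[1, 1] - minor[0, 1] * minor[1, 0]
            )
    A = cof.T / det
    r2 = q2 = 0.0
    for i in range(3):
        for j in range(i + 1, 3):
            q = -A[i, j] / np.sqrt(A[i, i] * A[j, j])
            r2 += R[i, j] ** 2
            q2 += q**2
    return r2 / (r2 + q2)
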