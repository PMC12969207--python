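"""Brute-force graph-metric oracle for small binary graphs.

Independent of the implementation under test: Floyd-Warshall for distances,
direct triangle counting for clustering.  Only sensible for n <= ~20.
"""

import numpy as np


def floyd_warshall(adj):
    n = adj.shape[0]
    D = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def clustering_coeff(adj):
    """Mean Watts-Strogatz node clustering via direct triangle count."""
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        tri = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a], nbrs[b]] > 0:
                    tri += 1
        vals.append(2.0 * tri / (k * (k - 1)))
    return float(np.mean(vals))


def char_path_length(adj):
    """Mean shortest path over connected ordered pairs; NaN if none."""
    D = floyd_warshall(adj)
    off = ~np.eye(adj.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    return float(D[finite].mean()) if finite.any() else np.nan


def global_efficiency(adj):
    """Mean inverse distance over all ordered pairs, disconnected -> 0."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    D = floyd_warshall(adj)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def local_efficiency(adj):
    """Mean over nodes of the global efficiency of the neighbor subgraph."""
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        sub = adj[np.ix_(nbrs, nbrs)]
        vals.append(global_efficiency(sub) if len(nbrs) >= 2 else 0.0)
    return float(np.mean(vals))


def nodal_efficiency(adj):
    n = adj.shape[0]
    D = floyd_warshall(adj)
    out = np.zeros(n)
    for i in range(n):
        inv = [1.0 / D[i, j] for j in range(n) if j != i and np.isfinite(D[i, j])]
        out[i] = sum(inv) / (n - 1) if n > 1 else 0.0
    return out


def degree(adj):
    return (adj > 0).sum(axis=1)


def random_graph(n, p, rng):
    """Symmetric binary ER graph with zero diagonal."""
    adj = (rng.random((n, n)) < p).astype(float)
    adj = np.triu(adj, 1)
    adj += adj.T
    return adj
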