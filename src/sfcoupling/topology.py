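"""Graph-topology validation metrics on thresholded functional networks.

Functional connectivity matrices are binarized by proportional thresholding
of the positive Fisher-z edges over a sparsity sweep (default 0.10-0.34 in
steps of 0.01, the convention of sparsity-sweep toolboxes), and each metric
is summarized per subject as the area under its sparsity curve (trapezoid),
which avoids committing to a single arbitrary threshold.

Global metrics: mean Watts-Strogatz clustering, characteristic path length
(mean shortest path over connected pairs; disconnected pairs excluded and
counted), global efficiency (mean inverse shortest path over all pairs,
disconnected contributing 0), local efficiency, and small-world statistics
gamma / lambda / sigma normalized against degree-preserving rewired graphs.
Nodal metrics: degree centrality and nodal efficiency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import _stat_table

logger = logging.getLogger(__name__)

GLOBAL_METRICS = (
    "sigma",
    "gamma",
    "lambda_ratio",
    "clustering",
    "char_path_length",
    "global_efficiency",
    "local_efficiency",
)
NODAL_METRICS = ("degree_centrality", "nodal_efficiency")


@dataclass
class ThresholdedGraph:
    adjacency: np.ndarray
    sparsity: float  # achieved retained-edge fraction


def threshold_proportional(fc_z: np.ndarray, sparsity: float) -> ThresholdedGraph:
    """Keep the top-k positive z edges of the upper triangle, symmetrized.

    ``k = round(sparsity * n(n-1)/2)``.  Ties at the cutoff are broken by the
    smaller (i, j) lexicographic index so the edge set is reproducible.
    Negative or zero edges are never retained; when fewer positive edges than
    k exist, all positives are kept and the achieved sparsity is logged.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    z = np.asarray(fc_z, float)
    n = z.shape[0]
    ii, jj = np.triu_indices(n, 1)
    vals = z[ii, jj]
    n_pairs = len(vals)
    k = int(round(sparsity * n_pairs))
    order = np.lexsort((jj, ii, -vals))  # by -z, then i, then j
    order = order[vals[order] > 0]
    if len(order) < k:
        logger.warning(
            "only %d positive edges for requested %d; achieved sparsity %.4f",
            len(order), k, len(order) / n_pairs,
        )
    keep = order[:k]
    adj = np.zeros((n, n))
    adj[ii[keep], jj[keep]] = 1.0
    adj += adj.T
    return ThresholdedGraph(adjacency=adj, sparsity=len(keep) / n_pairs)


def _as_adj(g) -> np.ndarray:
    return g.adjacency if isinstance(g, ThresholdedGraph) else np.asarray(g, float)


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path matrix of a binary graph (inf = disconnected)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    return shortest_path(csr_matrix(adj > 0), method="D", unweighted=True)


def _clustering(adj: np.ndarray) -> float:
    """Mean Watts-Strogatz node clustering: triangles over open triads."""
    A = (adj > 0).astype(float)
    deg = A.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", A, A, A)  # 2 * triangles per node
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return float(c.mean())


def _path_stats(adj: np.ndarray, D: np.ndarray | None = None):
    """(char path length over connected pairs, global efficiency, n disconnected)."""
    n = adj.shape[0]
    n_pairs = n * (n - 1)
    if n_pairs == 0:
        return np.nan, 0.0, 0
    if D is None:
        D = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    d = D[off]
    finite = np.isfinite(d)
    cpl = float(d[finite].mean()) if finite.any() else np.nan
    with np.errstate(divide="ignore"):
        inv = np.where(finite & (d > 0), 1.0 / d, 0.0)
    return cpl, float(inv.sum() / n_pairs), int(n_pairs - finite.sum())


def _local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph."""
    A = (adj > 0).astype(float)
    vals = []
    for i in range(A.shape[0]):
        nbrs = np.flatnonzero(A[i])
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        vals.append(_path_stats(sub)[1])
    return float(np.mean(vals))


def _rewired(
    adj: np.ndarray,
    rng: np.random.Generator,
    swaps_per_edge: int = 5,
    max_try_factor: int = 40,
) -> np.ndarray:
    """Degree-preserving randomization by Maslov-Sneppen double edge swaps.

    Each accepted swap replaces edges (a, b), (c, d) with (a, d), (c, b),
    rejecting self-loops and multi-edges; attempts are bounded, and falling
    far short of the target swap count is logged rather than fatal.
    """
    n = adj.shape[0]
    mask = adj > 0
    edges = [(int(i), int(j)) for i, j in np.argwhere(np.triu(mask, 1))]
    m = len(edges)
    if m < 2:
        return mask.astype(float)
    eset = set(edges)
    nswap = max(1, swaps_per_edge * m)
    max_tries = max_try_factor * nswap
    swaps = tries = 0
    chunk = 4096
    while swaps < nswap and tries < max_tries:
        pair_idx = rng.integers(0, m, size=(chunk, 2))
        coins = rng.random(chunk) < 0.5
        for (e1, e2), flip in zip(pair_idx.tolist(), coins.tolist()):
            tries += 1
            if swaps >= nswap or tries > max_tries:
                break
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if flip:
                c, d = d, c
            if a == c or a == d or b == c or b == d:
                continue
            new1 = (a, d) if a < d else (d, a)
            new2 = (c, b) if c < b else (b, c)
            if new1 in eset or new2 in eset:
                continue
            eset.discard(edges[e1])
            eset.discard(edges[e2])
            eset.add(new1)
            eset.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            swaps += 1
    if swaps < nswap // 2:
        logger.warning("rewiring achieved only %d of %d swaps", swaps, nswap)
    out = np.zeros((n, n))
    for a, b in eset:
        out[a, b] = out[b, a] = 1.0
    return out


def global_metrics(g, n_rand: int = 100, seed=None, smallworld: bool = True) -> dict:
    """Global network metrics; small-world normalization against rewired nulls.

    gamma = clustering / mean clustering of ``n_rand`` degree-preserving
    rewired graphs, lambda_ratio likewise for path length, sigma their ratio.
    """
    adj = _as_adj(g)
    if adj.sum() == 0:
        raise ValueError("graph has no edges")
    clustering = _clustering(adj)
    cpl, geff, n_disc = _path_stats(adj)
    if n_disc:
        logger.info("%d disconnected pairs excluded from path length", n_disc)
    leff = _local_efficiency(adj)
    out = {
        "clustering": clustering,
        "char_path_length": cpl,
        "global_efficiency": geff,
        "local_efficiency": leff,
    }
    if smallworld:
        if n_rand < 1:
            raise ValueError("n_rand must be >= 1")
        rng = np.random.default_rng(seed)
        cr, lr = [], []
        for _ in range(n_rand):
            H = _rewired(adj, rng)
            cr.append(_clustering(H))
            lr.append(_path_stats(H)[0])
        c_null = float(np.mean(cr))
        l_null = float(np.nanmean(lr))
        gamma = clustering / c_null if c_null > 0 else np.nan
        lam = cpl / l_null if l_null and np.isfinite(l_null) else np.nan
        out["gamma"] = gamma
        out["lambda_ratio"] = lam
        out["sigma"] = gamma / lam if lam and np.isfinite(lam) else np.nan
    return out


def nodal_metrics(g) -> pd.DataFrame:
    """Per-region degree centrality and nodal efficiency.

    Nodal efficiency of i is the mean of 1/d(i, j) over all j != i, with
    unreachable nodes contributing 0; an isolated node has efficiency 0.
    """
    adj = _as_adj(g)
    n = adj.shape[0]
    degree = (adj > 0).sum(axis=1).astype(int)
    D = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    eff = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)
    eff = np.where(off.any(axis=1), eff, 0.0)
    return pd.DataFrame(
        {"region_id": np.arange(n), "degree_centrality": degree, "nodal_efficiency": eff}
    )


def metric_auc(values: np.ndarray, sparsities: np.ndarray) -> float:
    """Trapezoidal area of a metric curve over the sparsity range."""
    return float(np.trapezoid(values, sparsities))


def subject_topology(
    fc_z: np.ndarray,
    sparsities,
    n_rand: int = 100,
    seed=None,
    smallworld: bool = True,
):
    """Per-subject AUC of every global and nodal metric over the sparsity sweep."""
    sparsities = np.asarray(sparsities, float)
    rng = np.random.default_rng(seed)
    glob_curves = {}
    n = fc_z.shape[0]
    nodal_curves = {m: np.zeros((len(sparsities), n)) for m in NODAL_METRICS}
    for si, s in enumerate(sparsities):
        g = threshold_proportional(fc_z, s)
        gm = global_metrics(
            g, n_rand=n_rand, seed=int(rng.integers(2**31)), smallworld=smallworld
        )
        for mname, v in gm.items():
            glob_curves.setdefault(mname, []).append(v)
        nm = nodal_metrics(g)
        nodal_curves["degree_centrality"][si] = nm["degree_centrality"].to_numpy(float)
        nodal_curves["nodal_efficiency"][si] = nm["nodal_efficiency"].to_numpy(float)
    glob_auc = {m: metric_auc(np.asarray(v), sparsities) for m, v in glob_curves.items()}
    nodal_auc = {
        m: np.trapezoid(curves, sparsities, axis=0) for m, curves in nodal_curves.items()
    }
    return glob_auc, nodal_auc, glob_curves


def topology_group_contrast(
    fc_list,
    meta,
    sparsities=None,
    n_rand: int = 100,
    seed=None,
    smallworld: bool = True,
    correction: str = "bonferroni",
):
    """Group contrast of per-subject metric AUCs with the standard covariates.

    Correction families: all global metrics together; regions per nodal metric.
    Returns (global stat table, dict of nodal stat tables, per-subject AUC
    tables for inspection).
    """
    if sparsities is None:
        sparsities = np.arange(0.10, 0.3401, 0.01)
    sparsities = np.asarray(sparsities, float)
    ss = np.random.SeedSequence(seed)
    glob_rows = []
    curve_rows = []
    nodal_rows = {m: [] for m in NODAL_METRICS}
    for si, (fc, child) in enumerate(zip(fc_list, ss.spawn(len(fc_list)))):
        g_auc, n_auc, curves = subject_topology(
            fc, sparsities, n_rand=n_rand,
            seed=child.generate_state(1)[0] % (2**31), smallworld=smallworld,
        )
        glob_rows.append(g_auc)
        for m in NODAL_METRICS:
            nodal_rows[m].append(n_auc[m])
        for mname, vals in curves.items():
            for s, v in zip(sparsities, vals):
                curve_rows.append(
                    {"subject_index": si, "sparsity": s, "metric": mname, "value": v}
                )
    glob_df = pd.DataFrame(glob_rows)
    gtab = _stat_table(list(glob_df.columns), glob_df.to_numpy(), meta, correction)
    ntabs = {}
    for m in NODAL_METRICS:
        arr = np.array(nodal_rows[m])
        units = [f"region{i}" for i in range(arr.shape[1])]
        tab = _stat_table(units, arr, meta, correction)
        tab.insert(0, "region_id", [units.index(u) for u in tab["unit"]])
        ntabs[m] = tab
    return gtab, ntabs, {
        "global_auc": glob_df,
        "nodal_auc": nodal_rows,
        "global_curves": pd.DataFrame(curve_rows),
    }
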