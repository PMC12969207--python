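"""Spatial correlation of the regional t-map with receptor density maps.

The unthresholded regional group-difference t-statistics are correlated
(Spearman, average ranks for ties) with each receptor/transporter density
map; significance is evaluated by uniformly permuting the region labels of
the t-map (the default when no spatial null model is supplied — spin-style
nulls can be passed as user-provided permutations), with an add-one
two-sided p on |rho| and BH-FDR correction across the map family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .stats import bh_fdr

logger = logging.getLogger(__name__)

#: the 19 PET-derived density maps conventionally tested together
DEFAULT_MAP_NAMES = (
    "5-HT1a", "5-HT1b", "5-HT2a", "5-HT4", "5-HT6", "SERT",
    "D1", "D2", "DAT", "F-DOPA", "NAT",
    "CB1", "CBF_ASL_MRI", "GABAa", "KappaOp", "MU", "NMDA", "VAChT", "mGluR5",
)


def _rank_z(v: np.ndarray) -> np.ndarray:
    """Average ranks standardized to zero mean / unit population variance."""
    r = rankdata(v)
    sd = r.std()
    if sd == 0:
        raise ValueError("constant vector has no rank correlation")
    return (r - r.mean()) / sd


def spatial_spearman(tmap: np.ndarray, density: np.ndarray) -> float:
    """Spearman rank correlation between two aligned regional vectors."""
    t = np.asarray(tmap, float).ravel()
    m = np.asarray(density, float).ravel()
    if t.shape != m.shape or len(t) < 3:
        raise ValueError("vectors must be aligned with >= 3 regions")
    try:
        zt, zm = _rank_z(t), _rank_z(m)
    except ValueError:
        logger.warning("constant input vector; Spearman undefined")
        return np.nan
    return float((zt * zm).mean())


def _perm_indices(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def permutation_p(
    tmap: np.ndarray,
    density: np.ndarray,
    n_perm: int = 5000,
    seed=None,
    permutations: np.ndarray | None = None,
) -> float:
    """Two-sided add-one permutation p for the Spearman correlation.

    Region labels of the t-map are shuffled uniformly unless explicit
    ``permutations`` (n_perm x n_regions index rows) are supplied.
    """
    t = np.asarray(tmap, float).ravel()
    m = np.asarray(density, float).ravel()
    obs = spatial_spearman(t, m)
    if np.isnan(obs):
        return np.nan
    zt, zm = _rank_z(t), _rank_z(m)
    if permutations is None:
        permutations = _perm_indices(len(t), n_perm, np.random.default_rng(seed))
    else:
        permutations = np.asarray(permutations, int)
        n_perm = permutations.shape[0]
    r = (zt[permutations] * zm).mean(axis=1)
    return float((1 + np.sum(np.abs(r) >= abs(obs) - 1e-12)) / (n_perm + 1))


def correlate_all_maps(
    tmap: np.ndarray,
    maps,
    n_perm: int = 5000,
    seed=None,
    alpha: float = 0.05,
    permutations: np.ndarray | None = None,
) -> pd.DataFrame:
    """Spearman rho, permutation p and BH-FDR q for every density map.

    ``maps`` is a regions x maps DataFrame (column names = map names) or
    array.  One shared set of t-map permutations is used across maps, and
    the FDR family is all maps tested in the run.
    """
    if isinstance(maps, pd.DataFrame):
        names = list(maps.columns)
        M = maps.to_numpy(float)
    else:
        M = np.asarray(maps, float)
        names = [f"map{k}" for k in range(M.shape[1])]
    t = np.asarray(tmap, float).ravel()
    if M.shape[0] != len(t):
        raise ValueError("maps and t-map must cover the same regions")
    if permutations is None:
        permutations = _perm_indices(len(t), n_perm, np.random.default_rng(seed))
    rows = []
    for name, col in zip(names, M.T):
        rho = spatial_spearman(t, col)
        p = (
            permutation_p(t, col, permutations=permutations)
            if np.isfinite(rho)
            else np.nan
        )
        rows.append({"map": name, "rho": rho, "perm_p": p})
    tab = pd.DataFrame(rows)
    ok = tab["perm_p"].notna().to_numpy()
    q = np.full(len(tab), np.nan)
    if ok.any():
        q[ok] = bh_fdr(tab.loc[ok, "perm_p"].to_numpy())
    tab["q"] = q
    tab["significant"] = tab["q"] < alpha
    return tab
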