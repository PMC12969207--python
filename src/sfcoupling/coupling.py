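"""Structure-function coupling (SFC) computation.

Functional connectivity (FC) is the Fisher-z transformed Pearson correlation
of regional time series.  Structural connectivity (SC) is a symmetric
fiber-count matrix.  The SFC of a region is the Pearson correlation between
the region's SC profile (optionally log-transformed, restricted to nonzero
fiber counts) and its FC profile over the same edges; network-block and
whole-brain SFC pool region pairs instead.

Conventions (all configurable where the literature is ambiguous):

* only edges with SC > 0 enter the coupling correlation — a zero fiber count
  carries no structural profile information;
* fiber counts are ``log(1 + count)`` transformed by default (heavy tails);
* negative FC z-values are retained;
* a region with fewer than ``min_edges`` nonzero SC edges gets a missing
  (NaN) coupling value rather than a meaningless correlation;
* the FC diagonal is 0 by convention and self-edges never enter.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import Atlas, CouplingVector

logger = logging.getLogger(__name__)

#: value correlations are clipped to when ``clip=True``
CLIP_BOUND = 1.0 - 1e-7


def fisher_z(r, clip: bool = False):
    """Variance-stabilizing Fisher transform ``z = arctanh(r)``.

    Parameters
    ----------
    r
        Correlation value(s) with ``|r| < 1`` (or any ``|r| <= 1`` when
        ``clip`` is set, in which case values are clipped to ``1 - 1e-7``).
    clip
        Clip out-of-domain correlations instead of raising.  Off by default:
        degenerate inputs should fail loudly.
    """
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -CLIP_BOUND, CLIP_BOUND)
    elif np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1; pass clip=True to clip at 1-1e-7")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def compute_fc(values: np.ndarray, clip: bool = False, region_names=None) -> np.ndarray:
    """Fisher-z functional connectivity matrix from a timepoints x regions array.

    The diagonal is set to 0 by convention.  A zero-variance column is
    rejected naming the offending region.
    """
    ts = np.asarray(values, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("time series must be a 2-D array with >= 2 timepoints")
    if not np.isfinite(ts).all():
        raise ValueError("time series contains non-finite values")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        idx = int(np.flatnonzero(sd == 0)[0])
        name = region_names[idx] if region_names is not None else idx
        raise ValueError(f"zero-variance time series for region {name}")
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 0.0)
    # floating error can push |r| marginally past 1 for collinear columns
    r = np.clip(r, -1.0, 1.0)
    off = ~np.eye(r.shape[0], dtype=bool)
    if not clip and np.any(np.abs(r[off]) >= 1.0):
        i, j = np.argwhere((np.abs(r) >= 1.0) & off)[0]
        raise ValueError(
            f"perfectly correlated regions {i} and {j} (|r| = 1); pass clip=True"
        )
    z = np.arctanh(np.clip(r, -CLIP_BOUND, CLIP_BOUND))
    np.fill_diagonal(z, 0.0)
    return z


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson r; NaN when either vector is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def sc_profile(sc: np.ndarray, log_transform: bool = True) -> np.ndarray:
    """Structural profile matrix used in coupling: ``log(1+counts)`` or raw."""
    sc = np.asarray(sc, float)
    return np.log1p(sc) if log_transform else sc


def regional_coupling(
    fc_z: np.ndarray,
    sc: np.ndarray,
    region: int,
    min_edges: int = 3,
    log_transform: bool = True,
):
    """SFC of one region: Pearson r between its SC and FC profiles.

    Returns ``(value, n_edges)`` where ``value`` is NaN when the region has
    fewer than ``min_edges`` nonzero structural edges or a degenerate profile.
    """
    if min_edges < 3:
        raise ValueError("min_edges must be >= 3")
    sc = np.asarray(sc, float)
    fc_z = np.asarray(fc_z, float)
    mask = sc[region] > 0
    mask[region] = False
    n_edges = int(mask.sum())
    if n_edges < min_edges:
        return np.nan, n_edges
    x = sc_profile(sc[region, mask], log_transform)
    y = fc_z[region, mask]
    r = _pearson(x, y)
    if np.isnan(r):
        logger.warning("region %d: zero-variance profile over %d edges", region, n_edges)
    return r, n_edges


def subject_coupling(
    fc_z: np.ndarray,
    sc: np.ndarray,
    atlas: Atlas,
    min_edges: int = 3,
    log_transform: bool = True,
    subject_id: str = "",
) -> CouplingVector:
    """Regional, network-block and whole-brain SFC for one subject.

    Network blocks pool every unordered region pair (i, j) with i in network a,
    j in network b, i != j and SC > 0; the whole-brain value pools all such
    pairs.  Blocks with fewer than ``min_edges`` qualifying pairs are missing.
    """
    fc_z = np.asarray(fc_z, float)
    sc = np.asarray(sc, float)
    n = atlas.n_regions
    if fc_z.shape != (n, n) or sc.shape != (n, n):
        raise ValueError("matrix shape does not match the atlas")
    regional = np.full(n, np.nan)
    n_edges = np.zeros(n, dtype=int)
    for i in range(n):
        regional[i], n_edges[i] = regional_coupling(
            fc_z, sc, i, min_edges=min_edges, log_transform=log_transform
        )
    iu = np.triu_indices(n, 1)
    present = sc[iu] > 0
    x_all = sc_profile(sc[iu][present], log_transform)
    y_all = fc_z[iu][present]
    net_lo = np.minimum(atlas.network_ids[iu[0]], atlas.network_ids[iu[1]])[present]
    net_hi = np.maximum(atlas.network_ids[iu[0]], atlas.network_ids[iu[1]])[present]
    k = atlas.n_networks
    block = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a, k):
            sel = (net_lo == a) & (net_hi == b)
            if sel.sum() < min_edges:
                logger.warning(
                    "network block (%d, %d): only %d qualifying pairs", a, b, sel.sum()
                )
                continue
            block[a, b] = block[b, a] = _pearson(x_all[sel], y_all[sel])
    whole = _pearson(x_all, y_all) if present.sum() >= min_edges else np.nan
    return CouplingVector(
        subject_id=subject_id,
        regional=regional,
        n_edges=n_edges,
        network_block=block,
        whole_brain=whole,
    )
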