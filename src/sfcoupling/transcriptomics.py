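"""Imaging transcriptomics: differential-stability filtering and PLS regression.

The regional group-difference t-map is regressed on a regions x genes
expression matrix with partial least squares.  Only the first component
(PLS1) is modeled: for a univariate response its weight vector is the
(normalized) covariance of each standardized gene with the standardized
response, and the PLS1 score is the corresponding gene-expression
combination per region.  Variance explained is defined on the response —
the squared Pearson correlation between the PLS1 score and the response —
and is tested by uniformly permuting the region assignment of the response.
Gene significance comes from bootstrap z-scores (weight / bootstrap SE over
region resamples) with BH-FDR control, split by weight sign into PLS+ and
PLS- lists.

Genes are pre-filtered by differential stability: the mean inter-donor
Spearman correlation of each gene's regional expression profile, keeping the
top fraction (default half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .stats import bh_fdr

logger = logging.getLogger(__name__)

_MAX_REDRAW = 10


def differential_stability(donor_values: np.ndarray) -> np.ndarray:
    """Per-gene mean inter-donor Spearman correlation of regional profiles.

    Parameters
    ----------
    donor_values
        Array of shape (n_donors, n_regions, n_genes).  A donor pair in
        which either profile is constant contributes a missing value for
        that gene; the mean is over the remaining pairs.
    """
    dv = np.asarray(donor_values, float)
    if dv.ndim != 3:
        raise ValueError("donor_values must be (n_donors, n_regions, n_genes)")
    d, n_regions, n_genes = dv.shape
    if d < 2:
        raise ValueError("differential stability needs >= 2 donors")
    if n_regions < 3:
        raise ValueError("differential stability needs >= 3 regions")
    ranks = rankdata(dv, axis=1)
    sd = ranks.std(axis=1)  # (d, g)
    const = sd == 0
    safe_sd = np.where(const, 1.0, sd)
    zr = (ranks - ranks.mean(axis=1, keepdims=True)) / safe_sd[:, None, :]
    pair_corrs = []
    for a in range(d):
        for b in range(a + 1, d):
            c = (zr[a] * zr[b]).mean(axis=0)
            c[const[a] | const[b]] = np.nan
            pair_corrs.append(c)
    pair_corrs = np.array(pair_corrs)
    n_bad = int(np.isnan(pair_corrs).sum())
    if n_bad:
        logger.warning("%d constant-profile donor pairs skipped in DS", n_bad)
    with np.errstate(invalid="ignore"):
        return np.nanmean(pair_corrs, axis=0)


def filter_top_fraction(ds: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    """Indices of genes with DS at or above the (1 - fraction) quantile.

    Ties at the boundary are all retained (count logged when that keeps more
    than the nominal number).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    ds = np.asarray(ds, float)
    if fraction == 1.0:
        return np.arange(len(ds))
    cut = np.nanquantile(ds, 1 - fraction)
    keep = np.flatnonzero(ds >= cut)
    nominal = int(np.ceil(fraction * len(ds)))
    if len(keep) > nominal:
        logger.warning(
            "DS ties at the cutoff: retaining %d genes (nominal %d)", len(keep), nominal
        )
    return keep


@dataclass
class PLSResult:
    weights: np.ndarray
    scores: np.ndarray
    varexp: float
    perm_p: float | None = None
    boot_se: np.ndarray | None = None
    z: np.ndarray | None = None
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    pls_plus: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    pls_minus: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _standardize_cols(M: np.ndarray, what: str = "column") -> np.ndarray:
    M = np.asarray(M, float)
    sd = M.std(axis=0)
    if np.any(sd == 0):
        idx = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"constant {what} at index {idx}")
    return (M - M.mean(axis=0)) / sd


def fit_pls1(X: np.ndarray, y: np.ndarray) -> PLSResult:
    """First PLS component of standardized expression against the response.

    The weight vector maximizes covariance between the X-score and y, which
    for a univariate response is ``w = X'y / ||X'y||`` after standardization.
    The sign is fixed so the score-response correlation is positive, and
    ``varexp`` is that correlation squared.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be regions x genes aligned with y")
    if X.shape[0] < 3:
        raise ValueError("PLS needs >= 3 regions")
    if y.std() == 0:
        raise ValueError("constant response vector")
    Xs = _standardize_cols(X, "gene column")
    ys = (y - y.mean()) / y.std()
    w = Xs.T @ ys
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("degenerate weights: X'y is identically zero")
    w = w / nrm
    scores = Xs @ w
    r = float(np.corrcoef(scores, ys)[0, 1])
    if r < 0:
        w, scores, r = -w, -scores, -r
    return PLSResult(weights=w, scores=scores, varexp=r * r)


def _varexp_perm(Xs: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized response-variance explained for many permuted responses.

    Y is regions x n_perm of already standardized responses.
    """
    S = Xs @ (Xs.T @ Y)  # scores up to positive scaling, regions x n_perm
    Sc = S - S.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    num = (Sc * Yc).sum(axis=0)
    den = np.linalg.norm(Sc, axis=0) * np.linalg.norm(Yc, axis=0)
    r = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return r**2


def pls_perm_test(X: np.ndarray, y: np.ndarray, n_perm: int = 5000, seed=None) -> float:
    """Add-one permutation p for PLS1 variance explained.

    Uniformly permutes the region assignment of the response (no spatial-
    autocorrelation preservation); ``perm_p = (1 + #{ve_perm >= ve_obs}) /
    (n_perm + 1)``.
    """
    fit = fit_pls1(X, y)
    Xs = _standardize_cols(np.asarray(X, float), "gene column")
    y = np.asarray(y, float).ravel()
    ys = (y - y.mean()) / y.std()
    rng = np.random.default_rng(seed)
    perms = np.column_stack([ys[rng.permutation(len(ys))] for _ in range(n_perm)])
    ve = _varexp_perm(Xs, perms)
    return float((1 + np.sum(ve >= fit.varexp - 1e-12)) / (n_perm + 1))


def _cov_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """PLS1 weights on the covariance scale: corr(gene, response) per gene.

    Proportional to the unit-norm weight vector of :func:`fit_pls1` but with
    a scale that is comparable across bootstrap replicates — renormalizing
    each replicate to unit norm would shrink the replicate spread (the norm
    itself grows with the resampling noise) and understate the SE.
    """
    Xs = _standardize_cols(X, "gene column")
    ys = (y - y.mean()) / y.std()
    return (Xs.T @ ys) / len(ys)


def pls_bootstrap(X: np.ndarray, y: np.ndarray, n_boot: int = 5000, seed=None):
    """Bootstrap SE and z-score of each PLS1 gene weight.

    Regions are resampled with replacement and the covariance-scale weight
    vector is recomputed per replicate, sign-aligned to the original fit
    (PLS weights are sign-indeterminate per replicate, and unaligned SEs
    would be inflated).  ``z = weight / bootstrap SE`` on that common scale.
    Degenerate replicates (constant response or gene column after
    resampling) are redrawn, bounded.
    """
    base = fit_pls1(X, y)  # validates inputs, fixes the sign convention
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    w0 = _cov_weights(X, y)
    if np.sign(w0 @ base.weights) < 0:  # match fit_pls1's sign convention
        w0 = -w0
    n = len(y)
    rng = np.random.default_rng(seed)
    W = np.empty((n_boot, X.shape[1]))
    n_redraw = 0
    for b in range(n_boot):
        for _ in range(_MAX_REDRAW):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.std() == 0:
                n_redraw += 1
                continue
            try:
                wb = _cov_weights(X[idx], yb)
                break
            except ValueError:
                n_redraw += 1
        else:
            raise RuntimeError("bootstrap replicate degenerate after bounded redraws")
        if wb @ w0 < 0:
            wb = -wb
        W[b] = wb
    if n_redraw:
        logger.info("redrew %d degenerate bootstrap replicates", n_redraw)
    se = W.std(axis=0, ddof=1)
    if np.any(se == 0):
        raise RuntimeError("zero bootstrap SE; increase n_boot")
    return se, w0 / se


def select_genes(weights: np.ndarray, z: np.ndarray, alpha: float = 0.05):
    """Two-sided normal p from z, BH-FDR q, and signed significant gene lists.

    PLS+ genes have positive weight (higher expression where the response is
    higher), PLS- negative; every listed gene has q < alpha.
    """
    z = np.asarray(z, float)
    if not np.isfinite(z).all():
        raise ValueError("z-scores must be finite")
    p = 2 * sps.norm.sf(np.abs(z))
    q = bh_fdr(p)
    sig = q < alpha
    plus = np.flatnonzero(sig & (np.asarray(weights) > 0))
    minus = np.flatnonzero(sig & (np.asarray(weights) < 0))
    return plus, minus, p, q


def pls_gene_association(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 5000,
    n_boot: int = 5000,
    alpha: float = 0.05,
    seed=None,
) -> PLSResult:
    """Full PLS1 analysis: fit, permutation test, bootstrap z, gene selection."""
    ss = np.random.SeedSequence(seed)
    s_perm, s_boot = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    res = fit_pls1(X, y)
    res.perm_p = pls_perm_test(X, y, n_perm=n_perm, seed=s_perm)
    res.boot_se, res.z = pls_bootstrap(X, y, n_boot=n_boot, seed=s_boot)
    res.pls_plus, res.pls_minus, res.p, res.q = select_genes(
        res.weights, res.z, alpha=alpha
    )
    return res
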