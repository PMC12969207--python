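"""Covariate-adjusted two-group inference and clinical correlations.

Group comparison is a single ordinary-least-squares GLM of the outcome on
[intercept, group indicator (patient = 1), age, education, mean framewise
displacement, handedness indicator (left = 1)] — ANCOVA-style rather than
residualize-then-test, which avoids bias when group correlates with the
covariates.  The statistic reported is the t of the group coefficient.

Multiple-testing correction is per analysis level: the whole-brain scalar is
its own family (size 1), the unique network blocks one family, and the
regions one family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import CouplingVector, meta_to_frame

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ["intercept", "group", "age", "education", "fd", "handedness"]


@dataclass(frozen=True)
class GLMResult:
    t: float
    df: int
    p_unc: float
    n_used: int


def design_matrix(meta) -> pd.DataFrame:
    """Design matrix [1, patient, age, education, fd, left-handed] per subject."""
    df = meta if isinstance(meta, pd.DataFrame) else meta_to_frame(meta)
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(df)),
            "group": (df["group"] == "patient").astype(float).to_numpy(),
            "age": df["age"].astype(float).to_numpy(),
            "education": df["education"].astype(float).to_numpy(),
            "fd": df["fd"].astype(float).to_numpy(),
            "handedness": (df["handedness"] == "left").astype(float).to_numpy(),
        }
    )
    if X.isna().to_numpy().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns {bad}")
    return X


def _check_rank(X: pd.DataFrame):
    A = X.to_numpy(float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # name the collinear columns via the rank-revealing QR diagonal
        _, R = np.linalg.qr(A)
        tol = np.abs(np.diag(R)).max() * max(A.shape) * np.finfo(float).eps
        bad = [X.columns[i] for i in range(A.shape[1]) if abs(R[i, i]) <= tol]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")


def group_glm_t(values, meta) -> GLMResult:
    """t-statistic of the patient-vs-control contrast, covariate adjusted.

    Subjects with a missing outcome are dropped pairwise (logged).  The
    residual degrees of freedom are ``n - 6`` for the full design.
    """
    X = design_matrix(meta)
    y = np.asarray(values, float)
    if y.shape[0] != len(X):
        raise ValueError("outcome length does not match subject table")
    keep = np.isfinite(y)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("group_glm_t: dropping %d subjects with missing outcome", n_drop)
    y = y[keep]
    X = X.loc[keep].reset_index(drop=True)
    for g, lab in ((1.0, "patient"), (0.0, "control")):
        if (X["group"] == g).sum() < 2:
            raise ValueError(f"fewer than 2 {lab} subjects with observed outcome")
    if np.ptp(y) == 0:
        raise ValueError("outcome has zero variance across subjects")
    constant = [
        c for c in X.columns
        if c not in ("intercept", "group") and X[c].nunique() == 1
    ]
    if constant:
        logger.info("dropping constant covariate columns: %s", constant)
        X = X.drop(columns=constant)
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    return GLMResult(
        t=float(fit.tvalues["group"]),
        df=int(fit.df_resid),
        p_unc=float(fit.pvalues["group"]),
        n_used=len(y),
    )


def bonferroni(p_unc, n_tests: int) -> np.ndarray:
    """Elementwise ``min(1, p * n_tests)``."""
    p = np.asarray(p_unc, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    out = np.minimum(1.0, p * n_tests)
    return float(out) if out.ndim == 0 else out


def bh_fdr(p_unc) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_unc, float)
    return multipletests(p, method="fdr_bh")[1]


def _stat_table(units, outcomes: np.ndarray, meta, correction: str) -> pd.DataFrame:
    """Run the group GLM per outcome column; one correction family per call."""
    rows = []
    skipped = []
    for unit, y in zip(units, outcomes.T):
        if np.isfinite(y).sum() < 4:
            skipped.append(unit)
            continue
        res = group_glm_t(y, meta)
        rows.append(
            {"unit": unit, "t": res.t, "df": res.df, "p_unc": res.p_unc, "n": res.n_used}
        )
    if skipped:
        logger.warning(
            "excluding %d units with (near-)all-missing outcome: %s; "
            "correction family reduced accordingly",
            len(skipped),
            skipped[:10],
        )
    tab = pd.DataFrame(rows)
    if tab.empty:
        raise ValueError("no testable units")
    n_tests = len(tab)
    if correction == "bonferroni":
        tab["p_corr"] = bonferroni(tab["p_unc"].to_numpy(), n_tests)
    elif correction == "fdr_bh":
        tab["p_corr"] = bh_fdr(tab["p_unc"].to_numpy())
    else:
        raise ValueError(f"unknown correction {correction!r}")
    tab["n_tests"] = n_tests
    return tab


def group_contrast_all_levels(
    couplings: list[CouplingVector],
    meta,
    atlas=None,
    correction: str = "bonferroni",
) -> dict:
    """Group GLM at whole-brain, network-block and regional level.

    Returns a dict of stat tables keyed ``whole_brain`` (family size 1),
    ``network`` (one row per unique block, family = K(K+1)/2) and
    ``regional`` (family = number of testable regions).
    """
    whole = np.array([[c.whole_brain for c in couplings]]).T
    wtab = _stat_table(["whole_brain"], whole, meta, correction)

    k = couplings[0].network_block.shape[0]
    names = (
        list(atlas.network_names)
        if atlas is not None
        else [f"net{a}" for a in range(k)]
    )
    block_units, block_cols = [], []
    for a in range(k):
        for b in range(a, k):
            block_units.append(f"{names[a]}-{names[b]}")
            block_cols.append([c.network_block[a, b] for c in couplings])
    ntab = _stat_table(block_units, np.array(block_cols).T, meta, correction)

    n = couplings[0].regional.shape[0]
    runits = (
        [atlas.region_names[i] for i in range(n)]
        if atlas is not None
        else [f"region{i}" for i in range(n)]
    )
    regional = np.array([c.regional for c in couplings])
    rtab = _stat_table(runits, regional, meta, correction)
    rtab.insert(0, "region_id", [runits.index(u) for u in rtab["unit"]])
    return {"whole_brain": wtab, "network": ntab, "regional": rtab}


def regional_tmap(regional_table: pd.DataFrame, n_regions: int) -> np.ndarray:
    """Unthresholded regional t-vector (NaN for untestable regions).

    This vector is the declared input contract for the transcriptomic and
    neurotransmitter-map association stages.
    """
    t = np.full(n_regions, np.nan)
    t[regional_table["region_id"].to_numpy(int)] = regional_table["t"].to_numpy(float)
    return t


def clinical_correlations(
    unit_values: pd.DataFrame,
    meta,
    score_names=None,
    patients_only: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of coupling with clinical scores.

    ``unit_values`` is subjects x units (indexed like ``meta``).  Computed
    within the patient group by default, matching how symptom-severity
    associations are usually reported.  Cells with fewer than 3 complete
    pairs are reported missing.  ``fdr=True`` adds BH q-values across all
    cells (off by default; conventional reporting is uncorrected p < 0.05).
    """
    mdf = meta if isinstance(meta, pd.DataFrame) else meta_to_frame(meta)
    mdf = mdf.reset_index(drop=True)
    vals = unit_values.reset_index(drop=True)
    if len(mdf) != len(vals):
        raise ValueError("unit_values and meta must describe the same subjects")
    if patients_only:
        sel = (mdf["group"] == "patient").to_numpy()
        mdf = mdf.loc[sel].reset_index(drop=True)
        vals = vals.loc[sel].reset_index(drop=True)
    base = {"subject_id", "group", "age", "education", "fd", "handedness"}
    if score_names is None:
        score_names = [c for c in mdf.columns if c not in base]
    rows = []
    for unit in vals.columns:
        x = vals[unit].to_numpy(float)
        for score in score_names:
            y = mdf[score].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                rows.append(
                    {"unit": unit, "score": score, "n": int(ok.sum()),
                     "r": np.nan, "p": np.nan}
                )
                continue
            if x[ok].std() == 0 or y[ok].std() == 0:
                rows.append(
                    {"unit": unit, "score": score, "n": int(ok.sum()),
                     "r": np.nan, "p": np.nan}
                )
                continue
            r, p = sps.pearsonr(x[ok], y[ok])
            rows.append(
                {"unit": unit, "score": score, "n": int(ok.sum()),
                 "r": float(r), "p": float(p)}
            )
    tab = pd.DataFrame(rows)
    if fdr:
        ok = tab["p"].notna()
        q = np.full(len(tab), np.nan)
        if ok.any():
            q[ok.to_numpy()] = bh_fdr(tab.loc[ok, "p"].to_numpy())
        tab["q"] = q
    return tab
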