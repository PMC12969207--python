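"""Tests for covariate-adjusted group inference and clinical correlations."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from sfcoupling import (
    bh_fdr,
    bonferroni,
    clinical_correlations,
    group_contrast_all_levels,
    group_glm_t,
)
from sfcoupling.types import CouplingVector, SubjectMeta


def make_meta(n_pat, n_con, rng, **overrides):
    metas = []
    for i in range(n_pat + n_con):
        metas.append(
            SubjectMeta(
                subject_id=f"s{i}",
                group="patient" if i < n_pat else "control",
                age=overrides.get("age", rng.uniform(18, 50)),
                education=rng.uniform(6, 19),
                fd=rng.uniform(0.05, 0.3),
                handedness="left" if rng.random() < 0.1 else "right",
                scores={},
            )
        )
    return metas


class TestGroupGLM:
    def test_zero_variance_outcome_rejected(self, rng):
        metas = make_meta(5, 5, rng)
        with pytest.raises(ValueError, match="zero variance"):
            group_glm_t(np.ones(10), metas)

    def test_collinear_design_named(self, rng):
        metas = make_meta(10, 10, rng)
        for m in metas:
            m.education = m.age  # education duplicates age
        with pytest.raises(ValueError, match="collinear"):
            group_glm_t(rng.standard_normal(20), metas)

    def test_missing_outcomes_dropped_pairwise(self, rng):
        metas = make_meta(10, 10, rng)
        y = rng.standard_normal(20)
        y[3] = np.nan
        res = group_glm_t(y, metas)
        assert res.n_used == 19
        assert res.df == 19 - 6

    def test_agrees_with_independent_ancova(self, rng):
        """The group t matches pingouin's ANCOVA F (t^2 = F) on random data."""
        metas = make_meta(20, 20, rng)
        y = rng.standard_normal(40) + 0.5 * np.array(
            [1 if m.group == "patient" else 0 for m in metas]
        )
        res = group_glm_t(y, metas)
        df = pd.DataFrame(
            {
                "y": y,
                "group": [m.group for m in metas],
                "age": [m.age for m in metas],
                "education": [m.education for m in metas],
                "fd": [m.fd for m in metas],
                "hand": [1.0 if m.handedness == "left" else 0.0 for m in metas],
            }
        )
        anc = pg.ancova(data=df, dv="y", between="group",
                        covar=["age", "education", "fd", "hand"])
        F = float(anc.loc[anc["Source"] == "group", "F"].iloc[0])
        assert res.t**2 == pytest.approx(F, rel=1e-8)

    def test_residualize_then_test_agrees_on_orthogonal_design(self, rng):
        """With covariates orthogonal to group, the joint-GLM group effect
        equals the group contrast of covariate-residualized outcomes."""
        n = 30
        covs = rng.standard_normal((n, 4))
        metas = make_meta(n, n, rng)
        for i, m in enumerate(metas):  # mirror covariates across groups
            m.age = 30 + 5 * covs[i % n, 0]
            m.education = 12 + 2 * covs[i % n, 1]
            m.fd = 0.15 + 0.02 * covs[i % n, 2]
            m.handedness = "right"
        y = rng.standard_normal(2 * n) + 0.4 * (np.arange(2 * n) < n)
        y += 0.3 * np.tile(covs[:, 0], 2)
        res = group_glm_t(y, metas)
        X = np.column_stack(
            [np.ones(2 * n)]
            + [[getattr(m, c) for m in metas] for c in ("age", "education", "fd")]
        )
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        diff = resid[:n].mean() - resid[n:].mean()
        import statsmodels.api as sm

        g = np.array([1.0 if m.group == "patient" else 0.0 for m in metas])
        beta = sm.OLS(y, np.column_stack([X, g])).fit().params[-1]
        assert beta == pytest.approx(diff, abs=1e-10)
        assert np.sign(res.t) == np.sign(diff)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 stays in [0.035, 0.065]."""
        rng = np.random.default_rng(7)
        metas = make_meta(100, 100, rng)
        rej = 0
        reps = 1000
        for _ in range(reps):
            res = group_glm_t(rng.standard_normal(200), metas)
            rej += res.p_unc < 0.05
        assert 0.035 <= rej / reps <= 0.065

    def test_power_on_planted_deficit_matches_noncentral_t(self):
        """Empirical power for a -1 SD deficit at n=40/40 (p < 0.001, t < 0)
        agrees with the closed-form noncentral-t prediction."""
        rng = np.random.default_rng(8)
        metas = make_meta(40, 40, rng)
        hits = 0
        reps = 200
        for _ in range(reps):
            y = rng.standard_normal(80)
            y[:40] -= 1.0
            res = group_glm_t(y, metas)
            hits += (res.t < 0) and (res.p_unc < 0.001)
        df = 80 - 6
        nc = -1.0 * np.sqrt(40 * 40 / 80)
        power = sps.nct.cdf(-sps.t.isf(0.0005, df), df, nc)
        assert hits / reps == pytest.approx(power, abs=0.08)
        assert hits / reps > 0.7


class TestCorrections:
    @pytest.mark.parametrize("p,n,expected", [
        (0.0001, 400, 0.04),
        (0.01, 400, 1.0),
        (0.05, 1, 0.05),
    ])
    def test_bonferroni_values(self, p, n, expected):
        assert bonferroni(p, n) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.integers(1, 500))
    def test_bonferroni_monotone(self, ps, n):
        ps = np.sort(np.asarray(ps))
        out = bonferroni(ps, n)
        assert np.all(np.diff(out) >= -1e-15)

    def test_bh_stepup_hand_computed(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)


class TestGroupContrastLevels:
    def _couplings(self, rng, n_sub, n_regions=10, k=2, drop_region=None):
        cvs = []
        for i in range(n_sub):
            reg = rng.standard_normal(n_regions) * 0.1 + 0.4
            if drop_region is not None:
                reg[drop_region] = np.nan
            block = rng.standard_normal((k, k)) * 0.1 + 0.4
            block = (block + block.T) / 2
            cvs.append(
                CouplingVector(
                    subject_id=f"s{i}", regional=reg,
                    n_edges=np.full(n_regions, 5),
                    network_block=block, whole_brain=0.4 + 0.1 * rng.standard_normal(),
                )
            )
        return cvs

    def test_family_sizes_per_level(self, rng):
        metas = make_meta(8, 8, rng)
        tabs = group_contrast_all_levels(self._couplings(rng, 16), metas)
        assert tabs["whole_brain"]["n_tests"].iloc[0] == 1
        assert tabs["network"]["n_tests"].iloc[0] == 3  # K(K+1)/2 for K=2
        assert len(tabs["network"]) == 3
        assert tabs["regional"]["n_tests"].iloc[0] == 10

    def test_all_missing_region_shrinks_family(self, rng):
        metas = make_meta(8, 8, rng)
        cvs = self._couplings(rng, 16, drop_region=4)
        tabs = group_contrast_all_levels(cvs, metas)
        assert len(tabs["regional"]) == 9
        assert tabs["regional"]["n_tests"].iloc[0] == 9
        assert 4 not in tabs["regional"]["region_id"].tolist()


class TestClinicalCorrelations:
    def _frame(self, vals):
        return pd.DataFrame({"sfc": vals})

    def test_affine_score_gives_unit_correlation(self, rng):
        metas = make_meta(10, 5, rng)
        vals = rng.standard_normal(15)
        for i, m in enumerate(metas):
            m.scores = {"ybocs_total": float(3 * vals[i] + 7)}
        tab = clinical_correlations(self._frame(vals), metas)
        assert tab["r"].iloc[0] == pytest.approx(1.0)
        assert tab["n"].iloc[0] == 10  # patients only

    def test_too_few_pairs_reported_missing(self, rng):
        metas = make_meta(4, 4, rng)
        vals = rng.standard_normal(8)
        for i, m in enumerate(metas):
            m.scores = {"bai": float(i) if i < 2 else np.nan}
        tab = clinical_correlations(self._frame(vals), metas, score_names=["bai"])
        assert np.isnan(tab["r"].iloc[0])

    def test_planted_association_recovered(self):
        """rho = 0.5 at n = 96 patients estimates r within [0.3, 0.7]."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 20
        for _ in range(reps):
            metas = make_meta(96, 10, rng)
            vals = rng.standard_normal(106)
            z = (vals - vals.mean()) / vals.std()
            for i, m in enumerate(metas):
                m.scores = {
                    "ybocs_total": float(0.5 * z[i] + np.sqrt(0.75) * rng.standard_normal())
                }
            tab = clinical_correlations(self._frame(vals), metas)
            hits += 0.3 <= tab["r"].iloc[0] <= 0.7
        assert hits / reps >= 0.9

    def test_independent_score_p_uniform(self):
        """p-values under independence pass a KS test against Uniform(0,1)."""
        rng = np.random.default_rng(12)
        metas = make_meta(96, 4, rng)
        ps = []
        for _ in range(1000):
            vals = rng.standard_normal(100)
            for m in metas:
                m.scores = {"sds": float(rng.standard_normal())}
            tab = clinical_correlations(self._frame(vals), metas, score_names=["sds"])
            ps.append(tab["p"].iloc[0])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_optional_fdr_column(self, rng):
        metas = make_meta(10, 5, rng)
        vals = rng.standard_normal(15)
        for m in metas:
            m.scores = {"bai": float(rng.standard_normal()),
                        "sds": float(rng.standard_normal())}
        tab = clinical_correlations(self._frame(vals), metas, fdr=True)
        assert "q" in tab.columns
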