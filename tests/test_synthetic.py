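"""Tests for the synthetic generators: contracts, determinism, planted truth."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from sfcoupling import (
    SimConfig,
    differential_stability,
    gen_atlas,
    gen_cohort,
    gen_expression,
    gen_receptor_maps,
    gen_structural,
    gen_subject_fc,
    subject_coupling,
)
from sfcoupling.coupling import regional_coupling


def small_config(**kw):
    base = dict(
        n_regions=20, n_networks=2, n_per_group=(6, 6), n_timepoints=100,
        sc_density=0.5, effect_regions=(15,), effect_delta=-0.3,
        n_genes=20, n_coupled_genes=4, n_inconsistent_genes=4,
        n_receptor_maps=5, coupled_map_indices=(1,), master_seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenAtlas:
    def test_small_construction(self):
        a = gen_atlas(8, 2, seed=1)
        assert a.n_regions == 8
        assert (a.hemisphere[:4] == "L").all() and (a.hemisphere[4:] == "R").all()
        for h in ("L", "R"):
            nets = set(a.network_ids[a.hemisphere == h])
            assert nets == {0, 1}

    def test_full_scale_split(self):
        a = gen_atlas(400, 7, seed=1)
        assert a.n_regions == 400 and a.n_networks == 7
        assert (a.hemisphere == "L").sum() == 200
        assert (a.hemisphere == "R").sum() == 200

    def test_deterministic(self):
        a1, a2 = gen_atlas(8, 2, seed=1), gen_atlas(8, 2, seed=1)
        assert a1.region_names == a2.region_names
        assert np.array_equal(a1.network_ids, a2.network_ids)

    def test_odd_region_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            gen_atlas(7, 2)


class TestGenStructural:
    def test_full_density_complete(self, atlas8):
        sc = gen_structural(atlas8, 1.0, seed=0)
        off = ~np.eye(8, dtype=bool)
        assert (sc[off] > 0).all()

    def test_symmetry_and_integer_counts(self, atlas8):
        sc = gen_structural(atlas8, 0.9, seed=5)
        assert np.array_equal(sc, sc.T)
        assert np.all(np.diag(sc) == 0)
        assert np.all(sc >= 0)
        assert np.array_equal(sc, np.round(sc))

    def test_density_within_window(self):
        a = gen_atlas(8, 2)
        sc = gen_structural(a, 0.5, seed=3)
        frac = (sc[np.triu_indices(8, 1)] > 0).mean()
        assert 0.40 <= frac <= 0.60

    def test_unreachable_density_rejected(self):
        a = gen_atlas(100, 2)
        with pytest.raises(ValueError):
            gen_structural(a, 0.005, seed=0)


class TestGenSubjectFC:
    def test_deterministic(self, atlas8):
        sc = gen_structural(atlas8, 1.0, seed=0)
        ts1, fc1 = gen_subject_fc(sc, np.full(8, 0.5), 50, seed=9)
        ts2, fc2 = gen_subject_fc(sc, np.full(8, 0.5), 50, seed=9)
        assert np.array_equal(ts1, ts2)
        assert np.array_equal(fc1, fc2)

    def test_out_of_range_targets_rejected(self, atlas8):
        sc = gen_structural(atlas8, 1.0, seed=0)
        with pytest.raises(ValueError):
            gen_subject_fc(sc, np.full(8, 1.0), 50, seed=0)

    def test_zero_mean_heterogeneous_targets_rejected(self, atlas8):
        sc = gen_structural(atlas8, 1.0, seed=0)
        t = np.array([0.4, -0.4] * 4)
        with pytest.raises(ValueError, match="zero"):
            gen_subject_fc(sc, t, 50, seed=0)

    @pytest.mark.parametrize("target,check", [
        (0.99, lambda v: (v > 0.9).all()),
        (0.5, lambda v: abs(v.mean() - 0.5) < 0.05),
        (0.0, lambda v: np.abs(v).mean() < 0.1),
    ])
    def test_planted_coupling_recovered_at_long_acquisition(self, target, check):
        """Measured regional SFC converges to the planted target (T = 10000)."""
        atlas = gen_atlas(200, 7)
        sc = gen_structural(atlas, 0.5, seed=2)
        _, fc = gen_subject_fc(sc, np.full(200, target), 10000, seed=0)
        cv = subject_coupling(fc, sc, atlas)
        assert check(cv.regional)


class TestGenCohort:
    def test_null_config_has_identical_truth(self):
        co = gen_cohort(small_config(effect_delta=0.0))
        gt = co.truth["group_targets"]
        assert np.array_equal(gt["patient"], gt["control"])

    def test_effect_confined_to_planted_region(self):
        co = gen_cohort(small_config(effect_regions=(5,), effect_delta=-0.3))
        diff = co.truth["group_targets"]["patient"] - co.truth["group_targets"]["control"]
        assert diff[5] == pytest.approx(-0.3)
        assert np.all(diff[np.arange(20) != 5] == 0)

    def test_deterministic_and_well_formed(self):
        c1 = gen_cohort(small_config())
        c2 = gen_cohort(small_config())
        assert np.array_equal(c1.subjects[0][0].fc_z, c2.subjects[0][0].fc_z)
        assert np.array_equal(c1.subjects[-1][0].sc, c2.subjects[-1][0].sc)
        for pair, meta in c1.subjects:
            assert pair.fc_z.shape == (20, 20)
            assert 18 <= meta.age <= 50
            assert meta.handedness in ("left", "right")
            assert set(meta.scores) >= {"ybocs_total", "bai", "bdi_ii", "sds"}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            small_config(effect_regions=(99,)).validate()
        with pytest.raises(ValueError):
            small_config(coupling_base=0.9, effect_delta=0.2).validate()

    def test_planted_score_association(self):
        cfg = small_config(n_regions=40, n_networks=4, n_per_group=(60, 6),
                           n_timepoints=400, effect_regions=(30,),
                           score_strength=0.6, master_seed=3)
        co = gen_cohort(cfg)
        vals, scores = [], []
        for pair, meta in co.subjects:
            if meta.group == "patient":
                vals.append(regional_coupling(pair.fc_z, pair.sc, 30)[0])
                scores.append(meta.scores["ybocs_compulsion"])
        r = np.corrcoef(vals, scores)[0, 1]
        assert 0.3 < r < 0.85


class TestGenExpression:
    def test_zero_noise_equals_standardized_map(self):
        atlas = gen_atlas(40, 4)
        rng = np.random.default_rng(0)
        pm = rng.standard_normal(20)
        expr = gen_expression(atlas, np.arange(20), 10, 3, pm, 4, 1.0, seed=1)
        z = (pm - pm.mean()) / pm.std()
        for d in range(3):
            for g in range(4):
                assert np.allclose(expr.donor_values[d, :, g], z)
        ds = differential_stability(expr.donor_values[:, :, :4])
        assert np.allclose(ds, 1.0)

    def test_uncoupled_genes_uncorrelated_with_map(self):
        atlas = gen_atlas(200, 4)
        rng = np.random.default_rng(1)
        pm = rng.standard_normal(100)
        expr = gen_expression(atlas, np.arange(100), 200, 1, pm, 0, 0.8, seed=2)
        cors = [
            abs(np.corrcoef(expr.values[:, g], pm)[0, 1]) for g in range(200)
        ]
        assert np.mean(cors) < 0.1

    def test_empty_region_mask_rejected(self):
        atlas = gen_atlas(40, 4)
        with pytest.raises(ValueError, match="region"):
            gen_expression(atlas, np.array([], int), 10, 2, np.array([]), 2, 0.8)


class TestGenReceptorMaps:
    def test_zero_noise_is_perfect_rank_correlation(self):
        atlas = gen_atlas(40, 4)
        pm = np.random.default_rng(0).standard_normal(40)
        maps = gen_receptor_maps(atlas, pm, 5, (0, 2), 1.0, seed=1)
        assert spearmanr(maps.iloc[:, 0], pm).statistic == pytest.approx(1.0)
        maps_neg = gen_receptor_maps(atlas, pm, 5, (0,), -1.0, seed=1)
        assert spearmanr(maps_neg.iloc[:, 0], pm).statistic == pytest.approx(-1.0)

    def test_nineteen_maps_get_canonical_names(self):
        atlas = gen_atlas(40, 4)
        pm = np.random.default_rng(0).standard_normal(40)
        maps = gen_receptor_maps(atlas, pm, 19, (1,), 0.5, seed=0)
        assert maps.shape == (40, 19)
        assert "5-HT1b" in maps.columns and "SERT" in maps.columns

    def test_coupled_index_validation(self):
        atlas = gen_atlas(40, 4)
        pm = np.random.default_rng(0).standard_normal(40)
        with pytest.raises(ValueError):
            gen_receptor_maps(atlas, pm, 5, (7,), 0.5, seed=0)
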