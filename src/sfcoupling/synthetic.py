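"""Synthetic cohorts, expression matrices and receptor maps with planted truth.

Every downstream stage of the pipeline gets a recovery test from this
module: cohorts with known regional coupling deficits in the patient group,
gene expression matrices in which a configurable subset of genes tracks a
planted spatial map across donors, and receptor density maps a subset of
which is rank-correlated with that map by construction.

Functional time series are generated from a target-covariance construction:
region i's connectivity profile is a blend of the (log-transformed,
standardized) structural profile and independent symmetric noise, with the
blend weight chosen per region so the profile correlation equals the target
coupling; the blended matrix is scaled, projected to the nearest positive-
definite correlation matrix (eigenvalue clipping plus diagonal rescaling)
and sampled as multivariate normal draws.  No neural dynamics are simulated
— this is the simplest mechanism with directly controllable coupling.

Determinism: every generator is a pure function of its seed; the cohort
generator splits one master ``SeedSequence`` into named child streams
(structural, functional, covariates, scores) in a fixed documented order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupling import compute_fc, regional_coupling
from .neuromaps import DEFAULT_MAP_NAMES
from .types import Atlas, ConnectomePair, SubjectMeta

logger = logging.getLogger(__name__)

_MAX_RETRY = 10

#: clinical score distributions (mean, sd) per group, loosely matched to the
#: symptom ranges of a moderate-severity medication-free cohort
SCORE_DISTRIBUTIONS = {
    "ybocs_total": ((25.0, 5.0), (2.0, 1.5)),
    "ybocs_obsession": ((13.0, 3.0), (1.0, 1.0)),
    "ybocs_compulsion": ((12.0, 3.0), (1.0, 1.0)),
    "ocir_washing": ((6.0, 2.0), (1.0, 1.0)),
    "ocir_checking": ((6.0, 2.0), (1.0, 1.0)),
    "ocir_ordering": ((6.0, 2.0), (1.0, 1.0)),
    "ocir_hoarding": ((5.0, 2.0), (1.0, 1.0)),
    "bai": ((18.0, 7.0), (4.0, 3.0)),
    "bdi_ii": ((16.0, 8.0), (4.0, 3.0)),
    "sds": ((15.0, 5.0), (2.0, 2.0)),
}


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate a two-group resting-state design: 96 patients vs 84
    controls on a 400-region / 7-network parcellation, one right-hemisphere
    region with reduced patient coupling, and one symptom score planted to
    correlate with coupling in that region within the patient group.
    """

    n_regions: int = 400
    n_networks: int = 7
    n_per_group: tuple = (96, 84)  # (patients, controls)
    n_timepoints: int = 200
    sc_density: float = 0.3
    coupling_base: float = 0.45
    effect_regions: tuple = (350,)
    effect_delta: float = -0.3
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age": -0.002,        # per year
            "education": 0.004,   # per year
            "fd": -0.3,           # per mm mean framewise displacement
            "handedness": -0.02,  # left-handed offset
        }
    )
    subject_sd: float = 0.08  # between-subject coupling jitter
    score_name: str = "ybocs_compulsion"
    score_region: int | None = None  # defaults to the first effect region
    score_strength: float = 0.5
    n_genes: int = 2000
    n_donors: int = 6
    n_coupled_genes: int = 100
    gene_loading: float = 0.8
    n_inconsistent_genes: int = 200
    n_receptor_maps: int = 19
    coupled_map_indices: tuple = (1, 5)  # 5-HT1b and SERT under the default names
    receptor_strength: float = -0.4
    master_seed: int = 0

    def validate(self):
        if self.n_regions < 2 or self.n_regions % 2:
            raise ValueError("n_regions must be an even count >= 2")
        for name in ("n_networks", "n_timepoints", "n_genes", "n_donors",
                     "n_receptor_maps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if min(self.n_per_group) < 1:
            raise ValueError("each group needs >= 1 subject")
        if not 0 < self.sc_density <= 1:
            raise ValueError("sc_density must lie in (0, 1]")
        if self.sc_density * (self.n_regions - 1) < 3:
            raise ValueError("sc_density too low for >= 3 edges per region")
        if not 0 < self.coupling_base < 1:
            raise ValueError("coupling_base must lie in (0, 1)")
        if not -1 < self.coupling_base + self.effect_delta < 1:
            raise ValueError("coupling_base + effect_delta must lie in (-1, 1)")
        bad = [r for r in self.effect_regions if not 0 <= r < self.n_regions]
        if bad:
            raise ValueError(f"effect_regions out of range: {bad}")
        if self.n_coupled_genes > self.n_genes:
            raise ValueError("n_coupled_genes exceeds n_genes")
        if not 0 <= abs(self.gene_loading) <= 1:
            raise ValueError("gene_loading must lie in [-1, 1]")
        bad = [m for m in self.coupled_map_indices
               if not 0 <= m < self.n_receptor_maps]
        if bad:
            raise ValueError(f"coupled_map_indices out of range: {bad}")
        if not 0 <= abs(self.receptor_strength) <= 1:
            raise ValueError("receptor_strength must lie in [-1, 1]")
        return self


@dataclass
class SyntheticCohort:
    atlas: Atlas
    subjects: list  # of (ConnectomePair, SubjectMeta)
    truth: dict
    timeseries: list = field(default_factory=list)  # per-subject T x regions


def gen_atlas(n_regions: int, n_networks: int, seed=0) -> Atlas:
    """Toy parcellation: L/R halves, networks in contiguous blocks per hemisphere.

    Deterministic given its arguments (the seed is accepted for interface
    uniformity with the other generators).
    """
    if n_regions % 2:
        raise ValueError("n_regions must be even (split into L/R halves)")
    if n_networks > n_regions // 2:
        raise ValueError("n_networks cannot exceed regions per hemisphere")
    half = n_regions // 2
    hemi = np.array(["L"] * half + ["R"] * half)
    blocks = np.concatenate(
        [np.full(len(chunk), k) for k, chunk in
         enumerate(np.array_split(np.arange(half), n_networks))]
    )
    nets = np.concatenate([blocks, blocks])
    network_names = tuple(f"net{k}" for k in range(n_networks))
    names = tuple(
        f"{h}_{network_names[nets[i]]}_{i}" for i, h in enumerate(hemi)
    )
    return Atlas(region_names=names, hemisphere=hemi,
                 network_ids=nets, network_names=network_names)


def gen_structural(atlas: Atlas, density: float, seed=None) -> np.ndarray:
    """Symmetric fiber-count matrix: random support at the exact requested
    density, rounded-lognormal counts.

    Heavy-tailed counts mimic tract-count distributions without anatomical
    modeling.  Regenerates (bounded) until every region has >= 3 edges.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n = atlas.n_regions
    rng = np.random.default_rng(seed)
    n_pairs = n * (n - 1) // 2
    k = max(1, int(round(density * n_pairs)))
    # seed every region with 3 edges first, then fill to the exact count
    support = np.zeros((n, n), dtype=bool)
    for i in rng.permutation(n):
        deficit = 3 - int(support[i].sum())
        if deficit <= 0:
            continue
        candidates = np.setdiff1d(
            np.flatnonzero(~support[i]), [i], assume_unique=False
        )
        # pair up under-connected regions first to keep the seed set minimal
        needy = candidates[support[candidates].sum(axis=1) < 3]
        pick = rng.choice(needy, size=min(deficit, len(needy)), replace=False)
        if len(pick) < deficit:
            rest = np.setdiff1d(candidates, pick)
            pick = np.concatenate(
                [pick, rng.choice(rest, size=deficit - len(pick), replace=False)]
            )
        support[i, pick] = support[pick, i] = True
    iu = np.triu_indices(n, 1)
    n_seeded = int(support[iu].sum())
    if n_seeded > k:
        raise ValueError(
            f"density {density} cannot give every region >= 3 edges "
            f"(needs at least {n_seeded}/{n_pairs} pairs)"
        )
    free = np.flatnonzero(~support[iu])
    extra = rng.choice(free, size=k - n_seeded, replace=False)
    support[iu[0][extra], iu[1][extra]] = True
    support |= support.T
    counts = np.round(rng.lognormal(mean=3.0, sigma=1.0, size=k)) + 1
    sc = np.zeros((n, n))
    sel = np.flatnonzero(support[iu])
    sc[iu[0][sel], iu[1][sel]] = counts
    sc += sc.T
    return sc


def _blend_target_matrix(
    sc: np.ndarray, targets: np.ndarray, rng: np.random.Generator,
    log_transform: bool = True,
) -> np.ndarray:
    """Unit-variance planted matrix whose row-profile correlation with the
    structural profile equals the target coupling per region (on SC > 0 edges).

    Each edge blends the standardized structural profile with noise at
    ``c_ij = t_i * t_j / mean(t)``, which makes the expected row-profile
    correlation exactly ``t_i`` for any target vector with nonzero mean
    (the only shape a symmetric matrix cannot represent is a heterogeneous
    target vector averaging to zero, which is rejected).
    """
    n = sc.shape[0]
    t = np.clip(np.asarray(targets, float), -0.985, 0.985)
    if np.abs(t).max() < 1e-12:
        c = np.zeros((n, n))
    else:
        m = t.mean()
        if abs(m) < 1e-6:
            raise ValueError(
                "target coupling vector averages to zero; a symmetric FC "
                "construction cannot realize heterogeneous zero-mean targets"
            )
        c = np.clip(np.outer(t, t) / m, -0.985, 0.985)
    mask = (sc > 0) & ~np.eye(n, dtype=bool)
    prof = np.log1p(sc) if log_transform else sc.astype(float)
    mvals = prof[mask]
    s = np.zeros((n, n))
    s[mask] = (mvals - mvals.mean()) / mvals.std()
    noise = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    noise[iu] = rng.standard_normal(len(iu[0]))
    noise += noise.T
    F = np.where(mask, c * s + np.sqrt(1 - c**2) * noise, noise)
    np.fill_diagonal(F, 0.0)
    return F


def nearest_correlation(C: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and rescale the diagonal back to 1.

    The congruence rescaling preserves positive definiteness, so one pass
    suffices for sampling purposes.
    """
    vals, vecs = np.linalg.eigh(C)
    if vals.min() < eps:
        vals = np.clip(vals, eps, None)
        C = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C))
    if (d <= 0).any() or not np.isfinite(d).all():
        raise ValueError("positive-definite projection failed to converge")
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def gen_subject_fc(
    sc: np.ndarray,
    targets,
    n_timepoints: int,
    seed=None,
    amp_scale: float = 0.6,
    log_transform: bool = True,
):
    """Time series and empirical Fisher-z FC with planted regional coupling.

    ``amp_scale`` controls the off-diagonal magnitude of the target
    correlation matrix as ``amp_scale / sqrt(n_regions)``, the largest scale
    at which a dense random-sign structure stays near positive definite, so
    the planted profile correlations survive the projection.
    """
    sc = np.asarray(sc, float)
    n = sc.shape[0]
    targets = np.broadcast_to(np.asarray(targets, float), (n,))
    if np.any(np.abs(targets) >= 1):
        raise ValueError("target coupling values must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    F = _blend_target_matrix(sc, targets, rng, log_transform=log_transform)
    C = np.eye(n) + (amp_scale / np.sqrt(n)) * F
    C = nearest_correlation(C)
    L = np.linalg.cholesky(C)
    ts = rng.standard_normal((n_timepoints, n)) @ L.T
    fc_z = compute_fc(ts, clip=True)
    return ts, fc_z


def _covariates(n: int, rng: np.random.Generator):
    age = rng.uniform(18, 50, n)
    education = np.round(rng.uniform(6, 19, n))
    fd = np.clip(rng.lognormal(np.log(0.12), 0.4, n), 0.03, 0.5)
    handed = np.where(rng.random(n) < 0.1, "left", "right")
    return age, education, fd, handed


# reference points at which covariate effects are centered, so the group mean
# coupling stays at coupling_base
_COV_CENTER = {"age": 34.0, "education": 12.5, "fd": 0.12}


def gen_cohort(config: SimConfig) -> SyntheticCohort:
    """Two-group cohort with planted regional deficits and a planted
    symptom-coupling association.

    Patients' target coupling is ``coupling_base + effect_delta`` on the
    effect regions and ``coupling_base`` elsewhere; controls sit at
    ``coupling_base`` everywhere.  Covariates enter additively on the
    target-coupling scale (centered, with known coefficients), plus
    independent per-subject jitter.  Within the patient group, the named
    clinical score is generated to correlate at ``score_strength`` with the
    measured coupling of the score region; all other scores are group-typical
    independent noise.
    """
    config.validate()
    atlas = gen_atlas(config.n_regions, config.n_networks)
    ss = np.random.SeedSequence(config.master_seed)
    meta_ss, sc_ss, fc_ss, score_ss = ss.spawn(4)
    n_pat, n_con = config.n_per_group
    n_sub = n_pat + n_con
    groups = ["patient"] * n_pat + ["control"] * n_con

    meta_rng = np.random.default_rng(meta_ss)
    age, education, fd, handed = _covariates(n_sub, meta_rng)

    base = np.full(config.n_regions, config.coupling_base)
    patient_target = base.copy()
    patient_target[list(config.effect_regions)] += config.effect_delta
    group_truth = {"patient": patient_target, "control": base}

    ce = config.covariate_effects
    cov_shift = (
        ce.get("age", 0.0) * (age - _COV_CENTER["age"])
        + ce.get("education", 0.0) * (education - _COV_CENTER["education"])
        + ce.get("fd", 0.0) * (fd - _COV_CENTER["fd"])
        + ce.get("handedness", 0.0) * (handed == "left")
    )
    jitter = meta_rng.normal(0.0, config.subject_sd, n_sub)

    sc_children = sc_ss.spawn(n_sub)
    fc_children = fc_ss.spawn(n_sub)
    pairs = []
    timeseries = []
    subject_targets = np.empty((n_sub, config.n_regions))
    score_region = (
        config.score_region
        if config.score_region is not None
        else (config.effect_regions[0] if config.effect_regions else 0)
    )
    measured_at_score_region = np.full(n_sub, np.nan)
    for i in range(n_sub):
        target = np.clip(group_truth[groups[i]] + cov_shift[i] + jitter[i],
                         -0.95, 0.95)
        subject_targets[i] = target
        sc = gen_structural(atlas, config.sc_density, seed=sc_children[i])
        ts, fc_z = gen_subject_fc(sc, target, config.n_timepoints,
                                  seed=fc_children[i])
        sid = f"sub-{i:04d}"
        pairs.append(ConnectomePair(subject_id=sid, fc_z=fc_z, sc=sc))
        timeseries.append(ts)
        measured_at_score_region[i], _ = regional_coupling(fc_z, sc, score_region)

    score_rng = np.random.default_rng(score_ss)
    scores_table = {}
    for name, (pat_d, con_d) in SCORE_DISTRIBUTIONS.items():
        vals = np.where(
            np.array(groups) == "patient",
            score_rng.normal(*pat_d, n_sub),
            score_rng.normal(*con_d, n_sub),
        )
        scores_table[name] = np.clip(vals, 0, None)
    # plant the named association within the patient group
    rho = config.score_strength
    pat_idx = np.arange(n_pat)
    m = measured_at_score_region[pat_idx]
    if np.isfinite(m).all() and m.std() > 0 and abs(rho) > 0:
        zm = (m - m.mean()) / m.std()
        latent = rho * zm + np.sqrt(1 - rho**2) * score_rng.standard_normal(n_pat)
        mu, sd = SCORE_DISTRIBUTIONS[config.score_name][0]
        scores_table[config.score_name][pat_idx] = np.clip(mu + sd * latent, 0, None)

    subjects = []
    for i, pair in enumerate(pairs):
        meta = SubjectMeta(
            subject_id=pair.subject_id,
            group=groups[i],
            age=float(age[i]),
            education=float(education[i]),
            fd=float(fd[i]),
            handedness=str(handed[i]),
            scores={k: float(v[i]) for k, v in scores_table.items()},
        )
        subjects.append((pair, meta))

    truth = {
        "group_targets": group_truth,
        "subject_targets": subject_targets,
        "effect_regions": tuple(config.effect_regions),
        "effect_delta": config.effect_delta,
        "score_name": config.score_name,
        "score_region": score_region,
        "score_strength": config.score_strength,
    }
    return SyntheticCohort(atlas=atlas, subjects=subjects, truth=truth,
                           timeseries=timeseries)


@dataclass
class ExpressionMatrix:
    values: np.ndarray       # regions x genes, donor mean
    donor_values: np.ndarray  # donors x regions x genes
    gene_ids: tuple
    region_ids: np.ndarray   # atlas region indices covered


def gen_expression(
    atlas: Atlas,
    region_mask,
    n_genes: int,
    n_donors: int,
    planted_map,
    n_coupled: int,
    loading: float,
    seed=None,
    n_inconsistent: int = 0,
) -> ExpressionMatrix:
    """Donor-stacked expression with the first ``n_coupled`` genes tracking
    the planted spatial map.

    Coupled genes: each donor's profile is ``loading * z(map) + sqrt(1 -
    loading^2) * noise`` with donor-independent noise, so differential
    stability is high.  The next ``n_inconsistent`` genes get a structured
    profile drawn independently per donor (consistent within, inconsistent
    between donors); the rest are pure noise.
    """
    region_idx = np.flatnonzero(region_mask) if np.asarray(region_mask).dtype == bool \
        else np.asarray(region_mask, int)
    if len(region_idx) == 0:
        raise ValueError("region_mask selects no regions")
    if n_coupled > n_genes or n_coupled + n_inconsistent > n_genes:
        raise ValueError("gene class counts exceed n_genes")
    pm = np.asarray(planted_map, float)
    if pm.shape != (len(region_idx),):
        raise ValueError("planted_map must have one value per masked region")
    if pm.std() == 0:
        raise ValueError("planted_map is constant")
    zmap = (pm - pm.mean()) / pm.std()
    rng = np.random.default_rng(seed)
    n_r = len(region_idx)
    dv = rng.standard_normal((n_donors, n_r, n_genes))
    resid = np.sqrt(max(0.0, 1 - loading**2))
    dv[:, :, :n_coupled] = (
        loading * zmap[None, :, None]
        + resid * rng.standard_normal((n_donors, n_r, n_coupled))
    )
    if n_inconsistent:
        # one smooth profile per (donor, gene): coherent within a donor but
        # unrelated between donors, so DS stays near zero
        stop = n_coupled + n_inconsistent
        dv[:, :, n_coupled:stop] = rng.standard_normal(
            (n_donors, n_r, n_inconsistent)
        )
    gene_ids = tuple(
        [f"coupled{g:04d}" for g in range(n_coupled)]
        + [f"inconsistent{g:04d}" for g in range(n_inconsistent)]
        + [f"noise{g:04d}" for g in range(n_genes - n_coupled - n_inconsistent)]
    )
    return ExpressionMatrix(
        values=dv.mean(axis=0),
        donor_values=dv,
        gene_ids=gene_ids,
        region_ids=region_idx,
    )


def gen_receptor_maps(
    atlas: Atlas,
    planted_map,
    n_maps: int,
    coupled_indices,
    strength: float,
    seed=None,
    map_names=None,
) -> pd.DataFrame:
    """Receptor density maps; the coupled ones are rank-correlated with the
    planted map at roughly ``strength`` (signed), the rest independent noise."""
    pm = np.asarray(planted_map, float)
    if pm.std() == 0:
        raise ValueError("planted_map is constant")
    if map_names is None:
        map_names = (
            list(DEFAULT_MAP_NAMES) if n_maps == len(DEFAULT_MAP_NAMES)
            else [f"map{k}" for k in range(n_maps)]
        )
    bad = [m for m in coupled_indices if not 0 <= m < n_maps]
    if bad:
        raise ValueError(f"coupled_indices out of range: {bad}")
    zmap = (pm - pm.mean()) / pm.std()
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((len(pm), n_maps))
    resid = np.sqrt(max(0.0, 1 - strength**2))
    for k in coupled_indices:
        M[:, k] = strength * zmap + resid * rng.standard_normal(len(pm))
    return pd.DataFrame(M, columns=list(map_names))
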