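"""End-to-end orchestration: validation, stage execution, manifest.

Stage order mirrors the analysis: coupling -> group stats -> topology ->
PLS transcriptomics -> neurotransmitter maps -> clinical correlations.
Each stage writes delimited-text outputs under the run directory and later
stages read those intermediates, so a run is resumable stage by stage and a
stage-local option change (e.g. ``n_perm``) leaves upstream outputs
byte-identical.

Per-stage random seeds are derived from ``master_seed`` by spawning a fixed
number of ``SeedSequence`` children in a fixed order, so they do not depend
on which stages run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .coupling import compute_fc, subject_coupling
from .stats import (
    clinical_correlations,
    group_contrast_all_levels,
    regional_tmap,
)
from .topology import topology_group_contrast
from .transcriptomics import (
    differential_stability,
    filter_top_fraction,
    pls_gene_association,
)
from .neuromaps import correlate_all_maps
from .types import meta_to_frame

logger = logging.getLogger(__name__)

STAGES = ("coupling", "group_stats", "topology", "pls", "neuromap", "clinical")


@dataclass
class RunConfig:
    """Paths, analysis options and the master seed for one run."""

    atlas: str
    subjects: str
    timeseries_dir: str
    sc_dir: str
    out_dir: str
    expression_dir: str | None = None
    receptors: str | None = None
    min_edges: int = 3
    log_transform: bool = True
    fc_clip: bool = False
    sparsity_min: float = 0.10
    sparsity_max: float = 0.34
    sparsity_step: float = 0.01
    n_rand: int = 100
    smallworld: bool = True
    n_perm: int = 5000
    n_boot: int = 5000
    alpha: float = 0.05
    ds_fraction: float = 0.5
    correction: str = "bonferroni"
    clinical_scores: list = field(default_factory=list)
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def sparsities(self) -> np.ndarray:
        return np.arange(
            self.sparsity_min, self.sparsity_max + self.sparsity_step / 2,
            self.sparsity_step,
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _subject_files(config, metas):
    ts_dir, sc_dir = Path(config.timeseries_dir), Path(config.sc_dir)
    return [(m.subject_id, ts_dir / f"{m.subject_id}.tsv",
             sc_dir / f"{m.subject_id}.tsv") for m in metas]


def validate_inputs(config: RunConfig) -> dict:
    """Dimension, correspondence and covariate checks before anything runs.

    Returns ``{"errors": [...], "warnings": [...]}``; an empty error list
    means the pipeline may start.
    """
    errors, warnings = [], []
    for name in ("atlas", "subjects", "timeseries_dir", "sc_dir"):
        if not Path(getattr(config, name)).exists():
            errors.append(f"missing path for {name}: {getattr(config, name)}")
    if errors:
        return {"errors": errors, "warnings": warnings}
    atlas = io.read_atlas(config.atlas)
    metas = io.read_subjects(config.subjects)
    ids = [m.subject_id for m in metas]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        errors.append(f"duplicate subject ids: {sorted(dupes)}")
    n = atlas.n_regions
    for sid, ts_path, sc_path in _subject_files(config, metas):
        if not ts_path.exists():
            errors.append(f"subject {sid}: no time-series file {ts_path}")
            continue
        if not sc_path.exists():
            errors.append(f"subject {sid}: no SC file {sc_path}")
            continue
        ts, rid = io.read_matrix(ts_path)
        if ts.shape[1] != n or not np.array_equal(rid, np.arange(n)):
            errors.append(f"subject {sid}: time series does not match the atlas")
        sc, _ = io.read_matrix(sc_path)
        if sc.shape != (n, n):
            errors.append(f"subject {sid}: SC shape {sc.shape} != ({n}, {n})")
    mdf = meta_to_frame(metas)
    for col in ("age", "education", "fd"):
        miss = int(mdf[col].isna().sum())
        if miss:
            errors.append(f"{miss} subjects missing covariate {col!r}")
    if config.expression_dir is not None:
        if not Path(config.expression_dir).exists():
            errors.append(f"missing expression_dir {config.expression_dir}")
        else:
            _, region_ids, _ = io.read_expression(config.expression_dir)
            bad = [int(r) for r in region_ids if not 0 <= r < n]
            if bad:
                errors.append(f"expression region ids not in the atlas: {bad[:5]}")
    else:
        warnings.append("no expression_dir: PLS stage will be skipped")
    if config.receptors is not None:
        if not Path(config.receptors).exists():
            errors.append(f"missing receptors file {config.receptors}")
        else:
            _, rid = io.read_receptors(config.receptors)
            bad = [int(r) for r in rid if not 0 <= r < n]
            if bad:
                errors.append(f"receptor region ids not in the atlas: {bad[:5]}")
    else:
        warnings.append("no receptors file: neuromap stage will be skipped")
    if not 0 < config.sparsity_min < config.sparsity_max < 1:
        errors.append("sparsity range must satisfy 0 < min < max < 1")
    if config.min_edges < 3:
        errors.append("min_edges must be >= 3")
    return {"errors": errors, "warnings": warnings}


def _stage_coupling(config, atlas, metas, out):
    regional, nedges, whole, blocks = [], [], [], []
    block_names = None
    for sid, ts_path, sc_path in _subject_files(config, metas):
        ts, _ = io.read_matrix(ts_path)
        sc, _ = io.read_matrix(sc_path)
        fc_z = compute_fc(ts, clip=config.fc_clip)
        cv = subject_coupling(
            fc_z, sc, atlas, min_edges=config.min_edges,
            log_transform=config.log_transform, subject_id=sid,
        )
        regional.append(cv.regional)
        nedges.append(cv.n_edges)
        whole.append(cv.whole_brain)
        k = atlas.n_networks
        if block_names is None:
            block_names = [
                f"{atlas.network_names[a]}-{atlas.network_names[b]}"
                for a in range(k) for b in range(a, k)
            ]
        blocks.append(
            [cv.network_block[a, b] for a in range(k) for b in range(a, k)]
        )
    sids = [m.subject_id for m in metas]
    rdf = pd.DataFrame(np.array(regional),
                       columns=[str(i) for i in range(atlas.n_regions)])
    rdf.insert(0, "subject_id", sids)
    io.write_table(out / "coupling" / "regional.tsv", rdf)
    edf = pd.DataFrame(np.array(nedges),
                       columns=[str(i) for i in range(atlas.n_regions)])
    edf.insert(0, "subject_id", sids)
    io.write_table(out / "coupling" / "n_edges.tsv", edf)
    bdf = pd.DataFrame(np.array(blocks), columns=block_names)
    bdf.insert(0, "subject_id", sids)
    io.write_table(out / "coupling" / "network.tsv", bdf)
    wdf = pd.DataFrame({"subject_id": sids, "whole_brain": whole})
    io.write_table(out / "coupling" / "whole_brain.tsv", wdf)


def _read_couplings(out):
    rdf = io.read_table(out / "coupling" / "regional.tsv")
    bdf = io.read_table(out / "coupling" / "network.tsv")
    wdf = io.read_table(out / "coupling" / "whole_brain.tsv")
    return rdf, bdf, wdf


def _stage_group_stats(config, atlas, metas, out):
    from .types import CouplingVector

    rdf, bdf, wdf = _read_couplings(out)
    n = atlas.n_regions
    k = atlas.n_networks
    couplings = []
    block_cols = [c for c in bdf.columns if c != "subject_id"]
    for i in range(len(rdf)):
        block = np.full((k, k), np.nan)
        it = iter(bdf.loc[i, block_cols].to_numpy(float))
        for a in range(k):
            for b in range(a, k):
                block[a, b] = block[b, a] = next(it)
        couplings.append(
            CouplingVector(
                subject_id=str(rdf.loc[i, "subject_id"]),
                regional=rdf.loc[i, [str(j) for j in range(n)]].to_numpy(float),
                n_edges=np.zeros(n, int),
                network_block=block,
                whole_brain=float(wdf.loc[i, "whole_brain"]),
            )
        )
    tabs = group_contrast_all_levels(
        couplings, metas, atlas=atlas, correction=config.correction
    )
    io.write_table(out / "stats" / "whole_brain.tsv", tabs["whole_brain"])
    io.write_table(out / "stats" / "network.tsv", tabs["network"])
    io.write_table(out / "stats" / "regional.tsv", tabs["regional"])
    tmap = regional_tmap(tabs["regional"], n)
    io.write_table(
        out / "stats" / "tmap.tsv",
        pd.DataFrame({"region_id": np.arange(n), "t": tmap}),
    )


def _stage_topology(config, atlas, metas, out, seed):
    fcs = []
    for sid, ts_path, _ in _subject_files(config, metas):
        ts, _ = io.read_matrix(ts_path)
        fcs.append(compute_fc(ts, clip=config.fc_clip))
    gtab, ntabs, extras = topology_group_contrast(
        fcs, metas, sparsities=config.sparsities(), n_rand=config.n_rand,
        seed=seed, smallworld=config.smallworld, correction=config.correction,
    )
    io.write_table(out / "topology" / "global_stats.tsv", gtab)
    for m, tab in ntabs.items():
        io.write_table(out / "topology" / f"nodal_stats_{m}.tsv", tab)
    auc = extras["global_auc"].copy()
    auc.insert(0, "subject_id", [m.subject_id for m in metas])
    io.write_table(out / "topology" / "global_auc.tsv", auc)
    io.write_table(out / "topology" / "global_curves.tsv", extras["global_curves"])


def _load_tmap(out):
    df = io.read_table(out / "stats" / "tmap.tsv")
    return df["t"].to_numpy(float)


def _stage_pls(config, atlas, metas, out, seed):
    donor_stack, region_ids, gene_ids = io.read_expression(config.expression_dir)
    tmap = _load_tmap(out)
    y = tmap[region_ids]
    ok = np.isfinite(y)
    if (~ok).any():
        logger.info("PLS: dropping %d regions with missing t", int((~ok).sum()))
    y = y[ok]
    donor_stack = donor_stack[:, ok, :]
    if donor_stack.shape[0] >= 2:
        ds = differential_stability(donor_stack)
        keep = filter_top_fraction(ds, config.ds_fraction)
    else:
        ds = np.full(len(gene_ids), np.nan)
        keep = np.arange(len(gene_ids))
        logger.warning("single-donor expression: differential stability skipped")
    X = donor_stack.mean(axis=0)[:, keep]
    res = pls_gene_association(
        X, y, n_perm=config.n_perm, n_boot=config.n_boot,
        alpha=config.alpha, seed=seed,
    )
    lists = np.array(["ns"] * len(keep), dtype=object)
    lists[res.pls_plus] = "PLS+"
    lists[res.pls_minus] = "PLS-"
    genes = pd.DataFrame(
        {
            "gene": [gene_ids[g] for g in keep],
            "ds": ds[keep],
            "weight": res.weights,
            "boot_se": res.boot_se,
            "z": res.z,
            "p": res.p,
            "q": res.q,
            "list": lists,
        }
    )
    io.write_table(out / "pls" / "genes.tsv", genes)
    io.write_json(
        out / "pls" / "summary.json",
        {
            "varexp": res.varexp,
            "perm_p": res.perm_p,
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "alpha": config.alpha,
            "seed": seed,
            "n_genes_tested": int(len(keep)),
            "n_regions": int(len(y)),
            "n_plus": int(len(res.pls_plus)),
            "n_minus": int(len(res.pls_minus)),
        },
    )


def _stage_neuromap(config, atlas, metas, out, seed):
    maps, region_ids = io.read_receptors(config.receptors)
    tmap = _load_tmap(out)
    y = tmap[region_ids]
    ok = np.isfinite(y)
    if (~ok).any():
        logger.info("neuromap: dropping %d regions with missing t", int((~ok).sum()))
    tab = correlate_all_maps(
        y[ok], maps.loc[ok], n_perm=config.n_perm, seed=seed, alpha=config.alpha
    )
    io.write_table(out / "neuromap" / "maps.tsv", tab)
    io.write_json(
        out / "neuromap" / "summary.json",
        {
            "n_perm": config.n_perm,
            "seed": seed,
            "n_maps": int(len(tab)),
            "n_significant": int(tab["significant"].sum()),
            "alpha": config.alpha,
        },
    )


def _stage_clinical(config, atlas, metas, out):
    rdf, bdf, wdf = _read_couplings(out)
    reg_stats = io.read_table(out / "stats" / "regional.tsv")
    sig = reg_stats[reg_stats["p_unc"] < config.alpha]
    units = pd.DataFrame(index=range(len(wdf)))
    units["whole_brain"] = wdf["whole_brain"].to_numpy(float)
    for name in atlas.network_names:
        col = f"{name}-{name}"
        if col in bdf.columns:
            units[col] = bdf[col].to_numpy(float)
    for _, row in sig.iterrows():
        units[str(row["unit"])] = rdf[str(int(row["region_id"]))].to_numpy(float)
    scores = config.clinical_scores or None
    tab = clinical_correlations(units, metas, score_names=scores, patients_only=True)
    io.write_table(out / "clinical" / "correlations.tsv", tab)


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute the requested stages in order and write the run manifest.

    A stage failure halts all downstream stages; the manifest records the
    partial completion and the error message.
    """
    report = validate_inputs(config)
    if report["errors"]:
        raise ValueError("input validation failed:\n" + "\n".join(report["errors"]))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = io.read_atlas(config.atlas)
    metas = io.read_subjects(config.subjects)
    children = np.random.SeedSequence(config.master_seed).spawn(len(STAGES))
    stage_seed = {
        s: int(c.generate_state(1)[0] % 2**31) for s, c in zip(STAGES, children)
    }
    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = {
        "config_hash": config.hash(),
        "master_seed": config.master_seed,
        "stages": {},
        "warnings": report["warnings"],
        "files": [],
    }
    failed = False
    for stage in STAGES:
        if stage not in requested:
            manifest["stages"][stage] = {"status": "not requested"}
            continue
        if failed:
            manifest["stages"][stage] = {"status": "skipped: upstream failure"}
            continue
        if stage == "pls" and config.expression_dir is None:
            manifest["stages"][stage] = {"status": "skipped: no expression input"}
            continue
        if stage == "neuromap" and config.receptors is None:
            manifest["stages"][stage] = {"status": "skipped: no receptor input"}
            continue
        try:
            logger.info("stage %s: starting (seed %d)", stage, stage_seed[stage])
            if stage == "coupling":
                _stage_coupling(config, atlas, metas, out)
            elif stage == "group_stats":
                _stage_group_stats(config, atlas, metas, out)
            elif stage == "topology":
                _stage_topology(config, atlas, metas, out, stage_seed[stage])
            elif stage == "pls":
                _stage_pls(config, atlas, metas, out, stage_seed[stage])
            elif stage == "neuromap":
                _stage_neuromap(config, atlas, metas, out, stage_seed[stage])
            elif stage == "clinical":
                _stage_clinical(config, atlas, metas, out)
            manifest["stages"][stage] = {"status": "ok", "seed": stage_seed[stage]}
        except Exception as exc:  # noqa: BLE001 - manifest records the failure
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"status": f"failed: {exc}"}
            failed = True
    manifest["files"] = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        and p.name != "manifest.json"
    )
    io.write_json(out / "manifest.json", manifest)
    return manifest
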