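"""Delimited-text I/O for every artifact the pipeline reads or writes.

All tables are tab-separated with a header row.  Matrices (time series,
fiber counts) carry region ids as the header; stat tables are written with a
fixed float format so reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Atlas, frame_to_meta, meta_to_frame

SEP = "\t"
FLOAT_FORMAT = "%.10g"


def write_table(path, df: pd.DataFrame):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=SEP, index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP)


def write_matrix(path, M: np.ndarray, region_ids=None):
    M = np.asarray(M)
    if region_ids is None:
        region_ids = np.arange(M.shape[1])
    df = pd.DataFrame(M, columns=[str(r) for r in region_ids])
    write_table(path, df)


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    df = read_table(path)
    return df.to_numpy(float), np.array([int(c) for c in df.columns])


def write_atlas(path, atlas: Atlas):
    write_table(path, atlas.to_frame())


def read_atlas(path) -> Atlas:
    return Atlas.from_frame(read_table(path))


def write_subjects(path, metas):
    write_table(path, meta_to_frame(metas))


def read_subjects(path):
    return frame_to_meta(read_table(path))


def write_json(path, obj):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_cohort(cohort, out_dir):
    """Write a synthetic cohort in exactly the formats the pipeline reads,
    so a generated cohort is indistinguishable from a real one at the
    interface.  Returns the directory."""
    out = Path(out_dir)
    write_atlas(out / "atlas.tsv", cohort.atlas)
    write_subjects(out / "subjects.tsv", [m for _, m in cohort.subjects])
    if len(cohort.timeseries) != len(cohort.subjects):
        raise ValueError("cohort has no stored time series to write")
    for (pair, _), ts in zip(cohort.subjects, cohort.timeseries):
        write_matrix(out / "sc" / f"{pair.subject_id}.tsv", pair.sc)
        write_matrix(out / "timeseries" / f"{pair.subject_id}.tsv", ts)
    return out


def write_expression(out_dir, expr):
    """One file per donor plus the donor-mean matrix, rows keyed by region_id."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = ["region_id"] + list(expr.gene_ids)
    for d in range(expr.donor_values.shape[0]):
        df = pd.DataFrame(expr.donor_values[d], columns=list(expr.gene_ids))
        df.insert(0, "region_id", expr.region_ids)
        write_table(out / f"donor-{d + 1}.tsv", df)
    mean_df = pd.DataFrame(expr.values, columns=list(expr.gene_ids))
    mean_df.insert(0, "region_id", expr.region_ids)
    write_table(out / "donor-mean.tsv", mean_df)


def read_expression(expr_dir):
    """Read donor-*.tsv files back into (donor stack, region_ids, gene_ids)."""
    files = sorted(Path(expr_dir).glob("donor-[0-9]*.tsv"))
    if not files:
        raise FileNotFoundError(f"no donor-*.tsv files under {expr_dir}")
    stacks, region_ids, gene_ids = [], None, None
    for f in files:
        df = read_table(f)
        rid = df["region_id"].to_numpy(int)
        genes = [c for c in df.columns if c != "region_id"]
        if region_ids is None:
            region_ids, gene_ids = rid, genes
        elif not np.array_equal(rid, region_ids) or genes != gene_ids:
            raise ValueError(f"donor file {f} disagrees on regions or genes")
        stacks.append(df[genes].to_numpy(float))
    return np.array(stacks), region_ids, gene_ids


def write_receptors(path, maps: pd.DataFrame, region_ids=None):
    df = maps.copy()
    if region_ids is None:
        region_ids = np.arange(len(df))
    df.insert(0, "region_id", region_ids)
    write_table(path, df)


def read_receptors(path):
    df = read_table(path)
    rid = df["region_id"].to_numpy(int)
    return df.drop(columns="region_id"), rid
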