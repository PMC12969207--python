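"""Shared data containers for the coupling pipeline.

Region identifiers are 0-based and contiguous everywhere; an atlas table on
disk may additionally carry 1-based source labels as a separate column, but
in memory a region *is* its index into the atlas arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

VALID_GROUPS = ("patient", "control")
VALID_HEMISPHERES = ("L", "R")
VALID_HANDEDNESS = ("left", "right")


@dataclass(frozen=True)
class Atlas:
    """A parcellation: region names, hemisphere labels and network assignment.

    Parameters
    ----------
    region_names
        One label per region.
    hemisphere
        Array of ``"L"``/``"R"``, one per region.
    network_ids
        0-based index into ``network_names``, one per region.
    network_names
        Names of the functional networks (e.g. the canonical seven cortical
        networks used for within/between-network block analyses).
    """

    region_names: tuple
    hemisphere: np.ndarray
    network_ids: np.ndarray
    network_names: tuple

    def __post_init__(self):
        hemi = np.asarray(self.hemisphere)
        nets = np.asarray(self.network_ids, dtype=int)
        object.__setattr__(self, "region_names", tuple(self.region_names))
        object.__setattr__(self, "network_names", tuple(self.network_names))
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "network_ids", nets)
        n = len(self.region_names)
        if hemi.shape != (n,) or nets.shape != (n,):
            raise ValueError("atlas arrays must all have one entry per region")
        bad = set(np.unique(hemi)) - set(VALID_HEMISPHERES)
        if bad:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad)}")
        if nets.min(initial=0) < 0 or nets.max(initial=0) >= len(self.network_names):
            raise ValueError("network_ids out of range of network_names")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def hemisphere_mask(self, hemi: str) -> np.ndarray:
        return self.hemisphere == hemi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": np.arange(self.n_regions),
                "region_name": list(self.region_names),
                "hemisphere": self.hemisphere,
                "network_id": self.network_ids,
                "network_name": [self.network_names[k] for k in self.network_ids],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Atlas":
        df = df.sort_values("region_id").reset_index(drop=True)
        if not np.array_equal(df["region_id"].to_numpy(), np.arange(len(df))):
            raise ValueError("region_id must be contiguous 0-based")
        nets = df["network_id"].to_numpy(int)
        if "network_name" in df.columns:
            names = {}
            for nid, nname in zip(nets, df["network_name"]):
                names.setdefault(int(nid), str(nname))
            network_names = tuple(names[k] for k in range(max(names) + 1))
        else:
            network_names = tuple(f"net{k}" for k in range(nets.max() + 1))
        return cls(
            region_names=tuple(df["region_name"].astype(str)),
            hemisphere=df["hemisphere"].to_numpy(str),
            network_ids=nets,
            network_names=network_names,
        )


@dataclass
class SubjectMeta:
    """Demographics, motion and clinical scores for one subject."""

    subject_id: str
    group: str
    age: float
    education: float
    fd: float
    handedness: str
    scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}, got {self.group!r}")
        if self.handedness not in VALID_HANDEDNESS:
            raise ValueError(
                f"handedness must be one of {VALID_HANDEDNESS}, got {self.handedness!r}"
            )


@dataclass
class ConnectomePair:
    """One subject's functional (Fisher-z) and structural (fiber-count) matrices."""

    subject_id: str
    fc_z: np.ndarray
    sc: np.ndarray

    def __post_init__(self):
        fc = np.asarray(self.fc_z, float)
        sc = np.asarray(self.sc, float)
        if fc.shape != sc.shape or fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
            raise ValueError("fc_z and sc must be square matrices of the same size")
        self.fc_z = fc
        self.sc = sc

    @property
    def n_regions(self) -> int:
        return self.fc_z.shape[0]


@dataclass
class CouplingVector:
    """Structure-function coupling for one subject at all three levels.

    ``regional[i]`` is the Pearson correlation between region *i*'s structural
    and functional connectivity profiles over its nonzero structural edges
    (NaN when the region has fewer than ``min_edges`` such edges).
    ``network_block[a, b]`` pools all qualifying region pairs between networks
    *a* and *b*; ``whole_brain`` pools every qualifying pair.
    """

    subject_id: str
    regional: np.ndarray
    n_edges: np.ndarray
    network_block: np.ndarray
    whole_brain: float

    def __post_init__(self):
        reg = np.asarray(self.regional, float)
        finite = reg[np.isfinite(reg)]
        if finite.size and (np.abs(finite) > 1 + 1e-12).any():
            raise ValueError("regional coupling values must lie in [-1, 1]")
        self.regional = reg
        self.n_edges = np.asarray(self.n_edges, int)


def meta_to_frame(metas) -> pd.DataFrame:
    """Flatten a list of :class:`SubjectMeta` into a tidy table (scores as columns)."""
    rows = []
    for m in metas:
        row = {
            "subject_id": m.subject_id,
            "group": m.group,
            "age": m.age,
            "education": m.education,
            "fd": m.fd,
            "handedness": m.handedness,
        }
        row.update(m.scores)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_meta(df: pd.DataFrame) -> list:
    base = {"subject_id", "group", "age", "education", "fd", "handedness"}
    score_cols = [c for c in df.columns if c not in base]
    out = []
    for _, r in df.iterrows():
        scores = {c: float(r[c]) for c in score_cols if pd.notna(r[c])}
        out.append(
            SubjectMeta(
                subject_id=str(r["subject_id"]),
                group=str(r["group"]),
                age=float(r["age"]),
                education=float(r["education"]),
                fd=float(r["fd"]),
                handedness=str(r["handedness"]),
                scores=scores,
            )
        )
    return out
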