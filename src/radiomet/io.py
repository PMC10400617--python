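"""Core containers and text-format I/O.

Two-block omics data are carried as :class:`OmicsBlock` (a samples x features
``pandas.DataFrame`` plus a block kind), condition labels as a ``pandas.Series``
of ``"benign"`` / ``"malignant"`` strings indexed by sample id, and pathway
annotation as :class:`PathwayMap` (GMT-backed).

All on-disk formats are plain text: tab-delimited feature tables (first column
sample id, header row of feature ids), two-column label tables, and GMT for
pathway membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

BENIGN = "benign"
MALIGNANT = "malignant"
CONDITIONS = (BENIGN, MALIGNANT)

RADIOMICS = "radiomics"
METABOLITE = "metabolite"
BLOCK_KINDS = (RADIOMICS, METABOLITE)


class AlignmentError(ValueError):
    """Raised when two tables that must share ids do not."""


@dataclass
class OmicsBlock:
    """One samples x features numeric matrix with typed feature ids.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with feature ids as columns.
    kind:
        ``"radiomics"`` or ``"metabolite"``.
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}; expected one of {BLOCK_KINDS}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in block")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids in block")
        self.data = self.data.astype(float)

    # -- convenience accessors -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids: Iterable[str]) -> "OmicsBlock":
        ids = [f for f in feature_ids]
        missing = set(ids) - set(self.feature_ids)
        if missing:
            raise KeyError(f"features not in block: {sorted(missing)[:5]}...")
        return OmicsBlock(self.data.loc[:, ids].copy(), self.kind)

    def subset_samples(self, sample_ids: Iterable[str]) -> "OmicsBlock":
        ids = [s for s in sample_ids]
        return OmicsBlock(self.data.loc[ids].copy(), self.kind)

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.values).all())

    # -- I/O -------------------------------------------------------------------
    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index_label="sample_id")

    @classmethod
    def read(cls, path: str | Path, kind: str, sep: str = "\t") -> "OmicsBlock":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df, kind)


def check_aligned(a: OmicsBlock, b: OmicsBlock, features: bool = False) -> None:
    """Raise :class:`AlignmentError` unless sample (and optionally feature) ids match."""
    if a.sample_ids != b.sample_ids:
        raise AlignmentError("sample ids differ between blocks")
    if features and a.feature_ids != b.feature_ids:
        raise AlignmentError("feature ids differ between blocks")


def read_labels(path: str | Path, sep: str = "\t") -> pd.Series:
    df = pd.read_csv(path, sep=sep, index_col=0)
    labels = df.iloc[:, 0].astype(str)
    validate_labels(labels)
    labels.name = "condition"
    return labels


def write_labels(labels: pd.Series, path: str | Path, sep: str = "\t") -> None:
    labels.rename("condition").to_csv(path, sep=sep, index_label="sample_id")


def validate_labels(labels: pd.Series) -> None:
    bad = set(labels.unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"labels must be in {CONDITIONS}; found {sorted(bad)}")


@dataclass
class PathwayMap:
    """Pathway id -> member metabolite ids, with display names (GMT-style)."""

    members: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, mem in self.members.items():
            if not mem:
                raise ValueError(f"pathway {pid!r} has no members")
        for pid in self.members:
            self.names.setdefault(pid, pid)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.members)

    def restrict(self, universe: Iterable[str]) -> "PathwayMap":
        """Intersect every member set with *universe*, dropping emptied pathways."""
        uni = set(universe)
        members = {p: frozenset(m & uni) for p, m in self.members.items()}
        members = {p: m for p, m in members.items() if m}
        return PathwayMap(members, {p: self.names[p] for p in members})

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for pid, mem in self.members.items():
                fh.write("\t".join([pid, self.names.get(pid, pid), *sorted(mem)]) + "\n")

    @classmethod
    def read_gmt(cls, path: str | Path) -> "PathwayMap":
        members: dict[str, frozenset[str]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                members[parts[0]] = frozenset(p for p in parts[2:] if p)
                names[parts[0]] = parts[1]
        return cls(members, names)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, fanned out from one global seed."""
    import hashlib

    h = hashlib.blake2b(f"{stage}:{int(global_seed)}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)
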