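"""Readers and writers for the file formats the pipeline touches.

Four tabular/sequence formats are supported, all plain-text UTF-8:

* aligned FASTA of per-sample consensus strains (one record per sample),
* sample metadata TSV (``sample_id``, ``host``, ``study``, optional
  ``housing`` and ``age_years``),
* relative-abundance TSV (sample rows, taxon columns),
* square labelled distance-matrix TSV, with ``NA`` marking saturated
  (undefined) distances.

Every reader validates its invariants eagerly and raises on violation, so
downstream code can assume well-formed containers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SATURATED",
    "is_saturated",
    "AlignedStrainSet",
    "SampleTable",
    "AbundanceTable",
    "DistanceMatrix",
    "read_alignment",
    "read_sample_table",
    "read_abundance_table",
    "read_distance_matrix",
    "write_distance_matrix",
]

#: Marker for a saturated / undefined pairwise distance. Stored as NaN so
#: that numpy masking and nan-aware reductions apply directly; serialized
#: as the string "NA".
SATURATED: float = float("nan")

ALIGNMENT_ALPHABET = frozenset("ACGTN-")


def is_saturated(x: float) -> bool:
    """True if ``x`` is the SATURATED marker."""
    return isinstance(x, float) and math.isnan(x)


class AlignmentError(ValueError):
    """Raised when an input alignment violates a structural invariant."""


class MetadataJoinError(KeyError):
    """Raised when a record cannot be resolved against sample metadata."""


@dataclass(frozen=True)
class AlignedStrainSet:
    """Equal-length DNA alignment of sample-consensus strains, host-labelled.

    Parameters
    ----------
    strain_ids :
        Unique identifiers, one per strain (= one per sample).
    sequences :
        Aligned sequences over ``{A, C, G, T, N, -}``, stored upper-case.
    host_of :
        Map from strain id to host label (e.g. ``"cat"``).
    sgb_id :
        Free-text clade label for the species-level genome bin.
    """

    strain_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    host_of: Mapping[str, str]
    sgb_id: str = ""

    def __post_init__(self) -> None:
        if len(self.strain_ids) != len(self.sequences):
            raise AlignmentError("strain_ids and sequences differ in length")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise AlignmentError("duplicate strain ids in alignment")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentError("alignment has zero columns")
        for sid, seq in zip(self.strain_ids, self.sequences):
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise AlignmentError(
                    f"record {sid!r} contains illegal characters {sorted(bad)}; "
                    "allowed: A C G T N -"
                )
        missing = [s for s in self.strain_ids if s not in self.host_of]
        if missing:
            raise MetadataJoinError(
                f"strains without host label: {missing[:5]}"
            )

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def hosts(self) -> tuple[str, ...]:
        """Host label per strain, in strain order."""
        return tuple(self.host_of[s] for s in self.strain_ids)


@dataclass(frozen=True)
class SampleTable:
    """Per-sample metadata: host (required), study, housing, age."""

    frame: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("host",)
    OPTIONAL = ("study", "housing", "age_years")

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].unique()
            raise KeyError(f"duplicate sample ids: {list(dups[:5])}")
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"missing required column {col!r}")
        if self.frame["host"].isna().any():
            bad = self.frame.index[self.frame["host"].isna()]
            raise ValueError(f"samples with missing host: {list(bad[:5])}")
        if "age_years" in self.frame.columns:
            ages = pd.to_numeric(self.frame["age_years"], errors="coerce")
            if (ages.dropna() < 0).any():
                raise ValueError("negative age_years")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def host_of(self) -> dict[str, str]:
        return dict(self.frame["host"])

    def study_of(self) -> dict[str, str]:
        if "study" not in self.frame.columns:
            return {}
        return dict(self.frame["study"].dropna())


@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances with optional per-sample labels.

    ``data`` is a DataFrame indexed by sample id with taxon columns; values
    are nonnegative and each row sums to at most 1 (plus tolerance).
    """

    data: pd.DataFrame
    host_of: dict[str, str] = field(default_factory=dict)
    study_of: dict[str, str] = field(default_factory=dict)

    _ROW_SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise KeyError(f"duplicate sample rows: {list(dups[:5])}")
        if self.data.columns.has_duplicates:
            raise KeyError("duplicate taxon columns")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            self.data = self.data.fillna(0.0)
            values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("negative abundance value")
        sums = values.sum(axis=1)
        if (sums > 1.0 + self._ROW_SUM_TOL).any():
            bad = self.data.index[sums > 1.0 + self._ROW_SUM_TOL]
            raise ValueError(
                f"row sums exceed 1 for samples {list(bad[:5])}; "
                "expected relative abundances"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    def attach_metadata(self, metadata: SampleTable) -> "AbundanceTable":
        """Return a copy with host/study labels joined from ``metadata``."""
        missing = [s for s in self.sample_ids if s not in metadata.frame.index]
        if missing:
            raise MetadataJoinError(f"samples not in metadata: {missing[:5]}")
        host = metadata.host_of()
        study = metadata.study_of()
        return AbundanceTable(
            data=self.data.copy(),
            host_of={s: host[s] for s in self.sample_ids},
            study_of={s: study[s] for s in self.sample_ids if s in study},
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a saturation marker.

    ``values[i, j]`` is the distance between ``ids[i]`` and ``ids[j]``;
    NaN entries are SATURATED (distance undefined, e.g. the substitution
    model's log argument was non-positive).
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} ids"
            )
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite & finite.T],
            self.values.T[finite & finite.T],
            rtol=0,
            atol=1e-12,
        ) or not (finite == finite.T).all():
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        if (self.values[finite] < 0).any():
            raise ValueError("negative distance")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, label: str) -> int:
        return self.ids.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def saturated_mask(self) -> np.ndarray:
        """Boolean matrix, True where the entry is SATURATED."""
        return np.isnan(self.values)

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.index_of(x) for x in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_alignment(
    path: str | Path, metadata: SampleTable, sgb_id: str = ""
) -> AlignedStrainSet:
    """Read an aligned FASTA and attach host labels from ``metadata``.

    The FASTA record id (token before the first whitespace) must equal a
    sample id present in ``metadata``; there is one consensus strain per
    sample.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    host = metadata.host_of()
    unknown = [i for i in ids if i not in host]
    if unknown:
        raise MetadataJoinError(
            f"FASTA records not found in metadata: {unknown[:5]}"
        )
    return AlignedStrainSet(
        strain_ids=tuple(ids),
        sequences=tuple(seqs),
        host_of={i: host[i] for i in ids},
        sgb_id=sgb_id,
    )


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a tab-delimited metadata table keyed by ``sample_id``."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValueError("metadata table lacks a sample_id column")
    frame = frame.set_index("sample_id")
    return SampleTable(frame)


def read_abundance_table(path: str | Path) -> AbundanceTable:
    """Read a samples x taxa relative-abundance TSV; empty cells become 0."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame = frame.astype(float).fillna(0.0)
    return AbundanceTable(frame)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index_label="sample_id")


def write_distance_matrix(
    dm: DistanceMatrix, path: str | Path, scale: float = 1.0
) -> None:
    """Write a square labelled TSV; SATURATED entries become ``NA``.

    ``scale`` multiplies distances on output: 1 writes substitutions per
    site, 100 writes EMBOSS-distmat-style distances per 100 bases.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(("id", *dm.ids)) + "\n")
        for i, label in enumerate(dm.ids):
            cells = [
                "NA" if math.isnan(v) else f"{v * scale:.6f}"
                for v in dm.values[i]
            ]
            fh.write("\t".join((label, *cells)) + "\n")


def read_distance_matrix(path: str | Path, scale: float = 1.0) -> DistanceMatrix:
    """Read a labelled distance-matrix TSV; ``NA`` becomes SATURATED.

    Accepts either a full square matrix or a triangular (EMBOSS-distmat
    style) one, which is mirrored into the canonical square form. Values
    on disk are divided by ``scale``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(x) for x in frame.index)
    if tuple(str(c) for c in frame.columns) != ids:
        raise ValueError("distance matrix rows and columns disagree")
    values = frame.to_numpy(dtype=float) / scale
    # mirror a triangular dialect: where exactly one of (i,j)/(j,i) is
    # present, copy it across the diagonal
    missing = np.isnan(values)
    one_sided = missing & ~missing.T
    values[one_sided] = values.T[one_sided]
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids, values)
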