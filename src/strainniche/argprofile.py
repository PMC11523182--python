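"""Antibiotic-resistance-gene (ARG) filtering and drug-class aggregation.

Starts from a tabular protein-alignment hit table (CARD query proteins
against a gene-family catalogue, DIAMOND ``--outfmt 6`` columns including
``pident``, ``qcovhsp``, ``scovhsp``): hits are retained at >= 90%
identity with >= 80% mutual coverage (both query and subject), ARGs are
kept only when present (abundance > 0) in at least three samples of at
least one host, and retained ARG abundances are summed into the drug
classes they confer resistance to. An ARG mapping to several classes
contributes its full abundance to each (resistance classes overlap; the
class table is not a partition).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ArgHit",
    "read_diamond_hits",
    "filter_hits",
    "arg_presence_filter",
    "class_abundance",
    "DEFAULT_MIN_IDENTITY",
    "DEFAULT_MIN_COVERAGE",
    "DEFAULT_MIN_SAMPLES",
]

DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_MIN_COVERAGE = 80.0
DEFAULT_MIN_SAMPLES = 3

_HIT_COLUMNS = ("qseqid", "sseqid", "pident", "qcovhsp", "scovhsp")


@dataclass(frozen=True)
class ArgHit:
    """One protein alignment: CARD query vs gene-family subject."""

    query_id: str
    subject_id: str
    pident: float
    qcov: float
    scov: float

    def __post_init__(self) -> None:
        for name in ("pident", "qcov", "scov"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")


def read_diamond_hits(path: str | Path) -> list[ArgHit]:
    """Read a tab-delimited hit table with a header naming at least
    qseqid, sseqid, pident, qcovhsp, scovhsp (extra columns ignored)."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _HIT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"hit table lacks columns {missing}")
    return [
        ArgHit(str(r.qseqid), str(r.sseqid), r.pident, r.qcovhsp, r.scovhsp)
        for r in frame.itertuples()
    ]


def filter_hits(
    hits: Iterable[ArgHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[str]:
    """Subject (gene-family) ids passing identity and mutual coverage.

    A hit is retained when pident >= min_identity and BOTH query and
    subject coverage are >= min_coverage ("mutual" coverage). The result
    is the sorted, de-duplicated list of retained subject ids.
    """
    kept = {
        h.subject_id
        for h in hits
        if h.pident >= min_identity
        and h.qcov >= min_coverage
        and h.scov >= min_coverage
    }
    return sorted(kept)


def arg_presence_filter(
    abundance: pd.DataFrame,
    host_of: Mapping[str, str],
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> list[str]:
    """ARGs present (abundance > 0) in >= min_samples samples of one host.

    ``abundance`` is samples x ARG. Counting is per host: an ARG seen in
    two cats and two dogs only is dropped, because no single host reaches
    the floor.
    """
    if (abundance.to_numpy() < 0).any():
        raise ValueError("negative ARG abundance")
    missing = [s for s in abundance.index if s not in host_of]
    if missing:
        raise KeyError(f"samples without host label: {missing[:5]}")
    hosts = pd.Series({s: host_of[s] for s in abundance.index})
    counts = (abundance > 0).groupby(hosts).sum()
    keep = (counts >= min_samples).any(axis=0)
    return sorted(abundance.columns[keep])


def class_abundance(
    abundance: pd.DataFrame,
    class_map: Mapping[str, str | Sequence[str]],
) -> pd.DataFrame:
    """Sum ARG abundances into drug classes, per sample.

    ``class_map`` maps an ARG to one class or a sequence of classes; an
    ARG absent from the map lands in ``unclassified``. With a
    single-class map the per-sample class totals equal the per-sample ARG
    totals exactly; a multi-class ARG is counted in full once per class.
    """
    if (abundance.to_numpy() < 0).any():
        raise ValueError("negative ARG abundance")
    classes_of: dict[str, list[str]] = {}
    for arg in abundance.columns:
        mapped = class_map.get(arg, "unclassified")
        if isinstance(mapped, str):
            classes_of[arg] = [mapped]
        else:
            classes_of[arg] = list(mapped) or ["unclassified"]
    all_classes = sorted({c for cs in classes_of.values() for c in cs})
    out = pd.DataFrame(
        0.0, index=abundance.index.copy(), columns=all_classes
    )
    for arg, cs in classes_of.items():
        for c in cs:
            out[c] += abundance[arg]
    return out


def read_class_map(path: str | Path) -> dict[str, list[str]]:
    """Read an ARG -> drug-class TSV (columns arg_id, drug_class); an ARG
    may appear on several rows, one per class."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"arg_id", "drug_class"} <= set(frame.columns):
        raise ValueError("class map needs columns arg_id, drug_class")
    mapping: dict[str, list[str]] = {}
    for arg, grp in frame.groupby("arg_id", sort=True):
        mapping[str(arg)] = sorted(set(grp["drug_class"]))
    return mapping
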