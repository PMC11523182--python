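"""Rule-based genome and taxon screening.

The upstream bookkeeping of an assembly-based metagenome survey: grading
metagenome-assembled genomes (MAGs) by completeness/contamination,
assigning MAGs to known genome bins by Mash distance, deciding which
species-level genome bins (SGBs) count as present in a host, classifying
host-sharing patterns, and the minimum-genome rule for admitting novel
SGBs into a marker database. All thresholds default to the standard
values (high quality: >90% complete, <5% contaminated; bin levels at Mash
distance 5%/15%/30%; presence: abundance >= 1e-5 in >= 3 samples of a
host; novel SGB: >= 5 genomes) and comparisons are strict exactly as
stated, so boundary cases are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io import AbundanceTable

__all__ = [
    "MagRecord",
    "BinAssignment",
    "PresenceProfile",
    "classify_mag_quality",
    "assign_genome_bin",
    "presence_filter",
    "sharing_category",
    "novel_sgb_database_rule",
    "DEFAULT_MIN_ABUNDANCE",
    "DEFAULT_MIN_SAMPLES",
]

DEFAULT_MIN_ABUNDANCE = 1e-5
DEFAULT_MIN_SAMPLES = 3


@dataclass(frozen=True)
class MagRecord:
    mag_id: str
    completeness: float
    contamination: float
    grade: str


@dataclass(frozen=True)
class BinAssignment:
    mag_id: str
    nearest_bin_id: str
    nearest_distance: float
    level: str  # SGB | GGB | FGB | novel


@dataclass
class PresenceProfile:
    """Per-host presence and prevalence of one SGB."""

    sgb_id: str
    present: dict[str, bool]
    prevalence: dict[str, float]

    @property
    def sharing_category(self) -> str:
        return sharing_category(self)


def classify_mag_quality(completeness: float, contamination: float) -> str:
    """Grade a MAG: ``high``, ``medium`` or ``low``.

    high: completeness > 90 and contamination < 5;
    medium: completeness > 50 and contamination < 10;
    low: everything else (low/medium/high partition the input space).
    """
    if not 0 <= completeness <= 100:
        raise ValueError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0:
        raise ValueError(f"negative contamination {contamination}")
    if completeness > 90 and contamination < 5:
        return "high"
    if completeness > 50 and contamination < 10:
        return "medium"
    return "low"


def assign_genome_bin(
    distances: Mapping[str, float], mag_id: str = ""
) -> BinAssignment:
    """Assign a MAG to its nearest genome bin by Mash distance.

    Level is SGB (species) if the nearest distance is < 0.05, GGB (genus)
    if < 0.15, FGB (family) if < 0.30, otherwise novel. Ties on distance
    go to the lexicographically smallest bin id.
    """
    if not distances:
        raise ValueError("empty distance map")
    for b, d in distances.items():
        if not 0 <= d <= 1:
            raise ValueError(f"Mash distance {d} for bin {b!r} outside [0, 1]")
    best = min(distances, key=lambda b: (distances[b], b))
    d = distances[best]
    if d < 0.05:
        level = "SGB"
    elif d < 0.15:
        level = "GGB"
    elif d < 0.30:
        level = "FGB"
    else:
        level = "novel"
    return BinAssignment(mag_id, best, float(d), level)


def presence_filter(
    table: AbundanceTable,
    min_abundance: float = DEFAULT_MIN_ABUNDANCE,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> dict[str, PresenceProfile]:
    """Per-host presence and prevalence for every taxon in ``table``.

    A taxon is present in host h when at least ``min_samples`` of h's
    samples carry it at relative abundance >= ``min_abundance``;
    prevalence is the fraction of h's samples at or above the threshold.
    """
    if not table.host_of:
        raise ValueError("abundance table lacks host labels")
    hosts = sorted(set(table.host_of.values()))
    by_host = {
        h: [s for s in table.sample_ids if table.host_of[s] == h] for h in hosts
    }
    profiles: dict[str, PresenceProfile] = {}
    hit = table.data >= min_abundance
    for taxon in table.taxon_ids:
        present, prevalence = {}, {}
        for h in hosts:
            col = hit.loc[by_host[h], taxon]
            k = int(col.sum())
            present[h] = k >= min_samples
            prevalence[h] = k / len(by_host[h]) if by_host[h] else 0.0
        profiles[taxon] = PresenceProfile(taxon, present, prevalence)
    return profiles


#: Exact-set mapping from the set of hosts where an SGB is present to its
#: sharing category (cat/dog/human study design).
_CATEGORY = {
    frozenset(): "absent",
    frozenset({"cat"}): "cat-unique",
    frozenset({"dog"}): "dog-unique",
    frozenset({"human"}): "human-unique",
    frozenset({"cat", "dog"}): "companion-shared",
    frozenset({"cat", "human"}): "cat+human",
    frozenset({"dog", "human"}): "dog+human",
    frozenset({"cat", "dog", "human"}): "all-hosts",
}


def sharing_category(profile: PresenceProfile) -> str:
    """Host-sharing category from the exact set of hosts with presence."""
    hosts = frozenset(h for h, p in profile.present.items() if p)
    try:
        return _CATEGORY[hosts]
    except KeyError:
        raise ValueError(
            f"no category for host set {sorted(hosts)}; expected subsets of "
            "{cat, dog, human}"
        ) from None


def novel_sgb_database_rule(n_genomes: int, min_genomes: int = 5) -> bool:
    """Whether a novel SGB has enough genomes to enter the database."""
    if n_genomes < 0:
        raise ValueError("negative genome count")
    return n_genomes >= min_genomes


def screen_mag_table(mags: pd.DataFrame) -> pd.DataFrame:
    """Grade a MAG table (columns mag_id, completeness, contamination)."""
    out = mags.copy()
    out["grade"] = [
        classify_mag_quality(c, k)
        for c, k in zip(out["completeness"], out["contamination"])
    ]
    return out


def assign_bins_table(mash: pd.DataFrame) -> pd.DataFrame:
    """Assign every MAG in a long Mash table (mag_id, bin_id, distance)."""
    rows = []
    for mag_id, grp in mash.groupby("mag_id", sort=True):
        a = assign_genome_bin(
            dict(zip(grp["bin_id"], grp["distance"])), mag_id=str(mag_id)
        )
        rows.append(
            {
                "mag_id": a.mag_id,
                "nearest_bin_id": a.nearest_bin_id,
                "nearest_distance": a.nearest_distance,
                "level": a.level,
            }
        )
    return pd.DataFrame(rows)
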