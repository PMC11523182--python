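"""Host coherence (niche-association) scores for strain collections.

For a species-level genome bin (SGB) observed in several host species, the
coherence score quantifies how strongly its strains cluster by host. For
each host ``h`` with enough strains, let ``W`` be the pairwise genetic
distances among strains of ``h`` and ``B`` the distances from strains of
``h`` to strains of all other hosts. The host-specific score is the
clipped relative excess of between-host over within-host divergence,

    score_h = max(0, (median(B) - median(W)) / median(B)),

which is 0 when strains of ``h`` are as far from each other as from other
hosts' strains (well mixed) and approaches 1 when the host forms a tight,
distinct clade. The SGB's coherence score C is the unweighted mean of the
defined host-specific scores.

Scoring is restricted to SGBs that are shared across hosts and adequately
sampled: present in >= 20 samples overall, with >= 5 samples from each of
>= 2 hosts. Hosts below the 5-strain floor still contribute their strains
to other hosts' between-host pools but receive no score of their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import DistanceMatrix

__all__ = [
    "UNDEFINED",
    "EligibilityResult",
    "CoherenceResult",
    "eligible_sgbs",
    "host_score",
    "coherence_score",
    "results_table",
    "MIN_TOTAL_SAMPLES",
    "MIN_PER_HOST",
    "MIN_HOSTS",
]

#: Marker for an undefined host score (too many saturated pairs).
UNDEFINED: float = float("nan")

MIN_TOTAL_SAMPLES = 20
MIN_PER_HOST = 5
MIN_HOSTS = 2

#: A host score is undefined when more than this fraction of its relevant
#: pairs (within + between) is saturated.
MAX_SATURATED_FRACTION = 0.5


@dataclass(frozen=True)
class EligibilityResult:
    sgb_id: str
    eligible: bool
    reason: str = ""


@dataclass
class CoherenceResult:
    """Per-host niche scores and their unweighted mean for one SGB."""

    sgb_id: str
    host_scores: dict[str, float]
    mean_score: float
    n_per_host: dict[str, int] = field(default_factory=dict)
    eligible: bool = True
    reason: str = ""


def _check_eligibility(counts: Mapping[str, int]) -> tuple[bool, str]:
    positive = {h: c for h, c in counts.items() if c > 0}
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative strain count")
    total = sum(positive.values())
    if len(positive) < MIN_HOSTS:
        return False, f"present in {len(positive)} host(s); needs >= {MIN_HOSTS}"
    if total < MIN_TOTAL_SAMPLES:
        return False, f"only {total} samples; needs >= {MIN_TOTAL_SAMPLES}"
    deep = [h for h, c in positive.items() if c >= MIN_PER_HOST]
    if len(deep) < MIN_HOSTS:
        return False, (
            f"only {len(deep)} host(s) with >= {MIN_PER_HOST} samples; "
            f"needs >= {MIN_HOSTS}"
        )
    return True, ""


def eligible_sgbs(
    inventory: Mapping[str, Mapping[str, int]],
) -> list[EligibilityResult]:
    """Apply the sampling eligibility rules to an SGB -> host-count map.

    An SGB is eligible when it is shared across at least two hosts, seen in
    at least 20 samples in total, and has at least 5 samples in each of at
    least 2 hosts.
    """
    results = []
    for sgb_id, counts in inventory.items():
        ok, reason = _check_eligibility(counts)
        results.append(EligibilityResult(sgb_id, ok, reason))
    return results


def host_score(
    dm: DistanceMatrix,
    host_of: Mapping[str, str],
    h: str,
    max_saturated_fraction: float = MAX_SATURATED_FRACTION,
) -> float:
    """Host-specific coherence score for host ``h``.

    Returns UNDEFINED when more than ``max_saturated_fraction`` of the
    relevant pairs is saturated, or when no finite between-host distance
    exists. Requires >= 5 strains of ``h`` and at least one strain from
    another host.
    """
    own = [i for i, s in enumerate(dm.ids) if host_of[s] == h]
    other = [i for i, s in enumerate(dm.ids) if host_of[s] != h]
    if len(own) < MIN_PER_HOST:
        raise ValueError(
            f"host {h!r} has {len(own)} strains; needs >= {MIN_PER_HOST}"
        )
    if not other:
        raise ValueError(f"no strains outside host {h!r}")
    iu = np.triu_indices(len(own), k=1)
    within = dm.values[np.ix_(own, own)][iu]
    between = dm.values[np.ix_(own, other)].ravel()
    pool = np.concatenate([within, between])
    if np.isnan(pool).mean() > max_saturated_fraction:
        return UNDEFINED
    finite_b = between[np.isfinite(between)]
    finite_w = within[np.isfinite(within)]
    if finite_b.size == 0 or finite_w.size == 0:
        return UNDEFINED
    med_b = float(np.median(finite_b))
    if med_b == 0.0:
        return 0.0
    med_w = float(np.median(finite_w))
    return max(0.0, (med_b - med_w) / med_b)


def coherence_score(
    dm: DistanceMatrix,
    host_of: Mapping[str, str],
    sgb_id: str = "",
) -> CoherenceResult:
    """Coherence score for one SGB: mean of its defined host scores.

    Hosts with fewer than 5 strains contribute strains to other hosts'
    between-host pools but receive no score. Raises if no host reaches the
    5-strain floor.
    """
    counts: dict[str, int] = {}
    for s in dm.ids:
        counts[host_of[s]] = counts.get(host_of[s], 0) + 1
    eligible, reason = _check_eligibility(counts)
    scored_hosts = [h for h, c in sorted(counts.items()) if c >= MIN_PER_HOST]
    if not scored_hosts:
        raise ValueError("no host has >= 5 strains; cannot score")
    scores = {h: host_score(dm, host_of, h) for h in scored_hosts}
    defined = [v for v in scores.values() if not math.isnan(v)]
    if not defined:
        raise ValueError("all host scores undefined (saturation)")
    return CoherenceResult(
        sgb_id=sgb_id,
        host_scores=scores,
        mean_score=float(np.mean(defined)),
        n_per_host=counts,
        eligible=eligible,
        reason=reason,
    )


def results_table(results: list[CoherenceResult]) -> pd.DataFrame:
    """Flatten coherence results to a per-SGB table (scores at 3 decimals)."""
    hosts = sorted({h for r in results for h in r.n_per_host})
    rows = []
    for r in results:
        row: dict[str, object] = {"sgb_id": r.sgb_id}
        for h in hosts:
            row[f"n_{h}"] = r.n_per_host.get(h, 0)
        for h in hosts:
            s = r.host_scores.get(h)
            row[f"score_{h}"] = (
                round(s, 3) if s is not None and not math.isnan(s) else None
            )
        row["mean_score"] = round(r.mean_score, 3)
        row["eligible"] = r.eligible
        row["reason"] = r.reason
        rows.append(row)
    return pd.DataFrame(rows)
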