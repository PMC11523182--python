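"""Kimura 2-parameter (K2P/K80) distances with pairwise deletion.

The K80 model distinguishes transitions (A<->G, C<->T) from transversions.
For a sequence pair with ``n`` comparable sites, transition fraction
``P = ts/n`` and transversion fraction ``Q = tv/n``, the distance is

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Sites where either sequence carries ``N`` or ``-`` hold no information and
are excluded pair-by-pair (pairwise deletion). When the log argument is
non-positive the sequences are saturated and the distance is undefined;
this is reported as the SATURATED marker, never as an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import SATURATED, AlignedStrainSet, DistanceMatrix

__all__ = [
    "SiteCounts",
    "pair_counts",
    "k2p_distance",
    "distance_matrix",
    "DEFAULT_MIN_SITES",
]

#: Minimum number of comparable sites for a distance to be considered
#: estimable; shorter overlaps yield SATURATED.
DEFAULT_MIN_SITES = 100

# base encoding: A=0, C=1, G=2, T=3; N and '-' -> 4 (uninformative).
# Purines (A, G) are even, pyrimidines (C, T) odd, and the transition
# partner of code c is c ^ 2 — these facts drive the classification below.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SiteCounts:
    """Comparable-site, transition and transversion counts for one pair."""

    n: int
    ts: int
    tv: int

    def __post_init__(self) -> None:
        if not 0 <= self.ts + self.tv <= self.n:
            raise ValueError("ts + tv exceeds comparable sites")

    @property
    def P(self) -> float:
        """Transition fraction ts/n (0 when n = 0)."""
        return self.ts / self.n if self.n else 0.0

    @property
    def Q(self) -> float:
        """Transversion fraction tv/n (0 when n = 0)."""
        return self.tv / self.n if self.n else 0.0


def pair_counts(a: str | np.ndarray, b: str | np.ndarray) -> SiteCounts:
    """Count comparable sites, transitions and transversions for a pair.

    ``a`` and ``b`` may be strings or pre-encoded uint8 arrays. Sites where
    either sequence is ``N`` or ``-`` are dropped (pairwise deletion).
    """
    ca = encode_sequence(a) if isinstance(a, str) else a
    cb = encode_sequence(b) if isinstance(b, str) else b
    if ca.shape != cb.shape:
        raise ValueError(
            f"sequence lengths differ: {ca.shape[0]} vs {cb.shape[0]}"
        )
    comparable = (ca < 4) & (cb < 4)
    n = int(comparable.sum())
    diff = comparable & (ca != cb)
    # transition: both purines or both pyrimidines, i.e. same parity
    ts = int((diff & ((ca & 1) == (cb & 1))).sum())
    tv = int(diff.sum()) - ts
    return SiteCounts(n=n, ts=ts, tv=tv)


def k2p_distance(c: SiteCounts, min_sites: int = DEFAULT_MIN_SITES) -> float:
    """K2P distance from site counts, or SATURATED when undefined.

    SATURATED is returned when the pair overlaps on fewer than
    ``min_sites`` comparable sites, or when ``1 - 2P - Q <= 0`` or
    ``1 - 2Q <= 0`` (the correction diverges).
    """
    if c.n < min_sites:
        return SATURATED
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return SATURATED
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return max(d, 0.0)


def distance_matrix(
    strains: AlignedStrainSet, min_sites: int = DEFAULT_MIN_SITES
) -> DistanceMatrix:
    """All pairwise K2P distances for an alignment.

    SATURATED entries propagate from :func:`k2p_distance`; the diagonal is
    zero and the matrix is symmetric by construction.
    """
    if strains.n_strains < 2:
        raise ValueError("need at least 2 strains for a distance matrix")
    codes = [encode_sequence(s) for s in strains.sequences]
    n = strains.n_strains
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(pair_counts(codes[i], codes[j]), min_sites)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(strains.strain_ids, values)
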