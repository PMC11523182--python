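"""Bray-Curtis ordination and one-factor PERMANOVA.

Covers the community-composition workflow: Bray-Curtis dissimilarity of
relative-abundance profiles, classical PCoA (Gower double-centering and
eigendecomposition), a frequency correction that divides each sample's
principal-coordinate scores by the size of its group (used when host
cohorts differ greatly in sample count), abundance-weighted taxon
positions for annotating an ordination, and a single-factor permutation
PERMANOVA reporting R^2, the pseudo-F statistic and a permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import AbundanceTable, DistanceMatrix

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "bray_curtis",
    "pcoa",
    "frequency_correct",
    "feature_positions",
    "permanova",
]


@dataclass
class OrdinationResult:
    """PCoA axes: eigenvalues (non-increasing) and per-sample scores."""

    sample_ids: tuple[str, ...]
    eigenvalues: np.ndarray  # retained (positive) eigenvalues, length k
    scores: np.ndarray  # n x k, eigenvectors scaled by sqrt(eigenvalue)
    corrected: bool = False
    correction_divisor: dict[str, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=list(self.sample_ids), columns=cols)


@dataclass(frozen=True)
class PermanovaResult:
    R2: float
    pseudo_F: float
    p: float
    n_permutations: int
    seed: int


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    BC(x, y) = 1 - 2 * sum_j min(x_j, y_j) / (sum x + sum y); entries lie
    in [0, 1]. Every sample must have positive total abundance.
    """
    values = table.data.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"all-zero samples: {bad[:5]}")
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(tuple(table.sample_ids), d)


def pcoa(dm: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Classical PCoA (principal coordinates) of a distance matrix.

    The Gower matrix G = -1/2 * J D^2 J (J the centering matrix) is
    eigendecomposed; axes with non-positive eigenvalues are dropped and
    scores are eigenvectors scaled by sqrt(eigenvalue). Requesting more
    axes than have positive eigenvalues returns fewer, with a warning.
    """
    if np.isnan(dm.values).any():
        raise ValueError("PCoA requires a fully finite distance matrix")
    n = dm.n
    d2 = dm.values**2
    centered = np.eye(n) - np.full((n, n), 1.0 / n)
    gower = -0.5 * centered @ d2 @ centered
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12 if n else 0.0
    positive = eigvals > tol
    eigvals, eigvecs = eigvals[positive], eigvecs[:, positive]
    if k is not None:
        if k > eigvals.size:
            warnings.warn(
                f"requested {k} axes but only {eigvals.size} have positive "
                "eigenvalues; returning fewer",
                stacklevel=2,
            )
        eigvals, eigvecs = eigvals[:k], eigvecs[:, :k]
    scores = eigvecs * np.sqrt(eigvals)
    return OrdinationResult(
        sample_ids=tuple(dm.ids), eigenvalues=eigvals, scores=scores
    )


def frequency_correct(
    result: OrdinationResult,
    group_of: Mapping[str, str],
    group_sizes: Mapping[str, int] | None = None,
) -> OrdinationResult:
    """Divide each sample's scores by the size of its group.

    Compensates for unequal group sample sizes when displaying an
    ordination dominated by the largest cohort. ``group_sizes`` defaults
    to the observed counts in ``group_of``; passing it explicitly supports
    correction by cohort sizes larger than the plotted subset. Refuses to
    correct twice.
    """
    if result.corrected:
        raise ValueError("scores are already frequency-corrected")
    unknown = [s for s in result.sample_ids if s not in group_of]
    if unknown:
        raise KeyError(f"samples without a group: {unknown[:5]}")
    if group_sizes is None:
        group_sizes = {}
        for s in result.sample_ids:
            g = group_of[s]
            group_sizes[g] = group_sizes.get(g, 0) + 1
    divisors = {}
    for s in result.sample_ids:
        g = group_of[s]
        if g not in group_sizes or group_sizes[g] < 1:
            raise KeyError(f"group {g!r} has no size >= 1")
        divisors[s] = float(group_sizes[g])
    div = np.array([divisors[s] for s in result.sample_ids])
    return replace(
        result,
        scores=result.scores / div[:, None],
        corrected=True,
        correction_divisor=divisors,
    )


def feature_positions(
    result: OrdinationResult,
    table: AbundanceTable,
    taxa: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Abundance-weighted average ordination position per taxon.

    Position of taxon j on axis k is sum_i a[i,j] * s[i,k] / sum_i a[i,j],
    using the same (raw or corrected) scores as plotted. Taxa with zero
    total abundance get NaN coordinates.
    """
    if taxa is None:
        taxa = table.taxon_ids
    missing = [t for t in taxa if t not in table.data.columns]
    if missing:
        raise KeyError(f"taxa not in table: {missing[:5]}")
    aligned = table.data.loc[list(result.sample_ids), list(taxa)]
    weights = aligned.to_numpy(dtype=float)  # n x m
    totals = weights.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        positions = (weights.T @ result.scores) / totals[:, None]
    cols = [f"PC{i + 1}" for i in range(result.scores.shape[1])]
    return pd.DataFrame(positions, index=list(taxa), columns=cols)


def _permanova_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return float(ss_total), float(ss_within)


def permanova(
    dm: DistanceMatrix,
    labels: Mapping[str, str] | Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Partitions distance-based sums of squares by the grouping factor:
    R^2 = 1 - SS_within / SS_total and
    pseudo-F = (SS_between / (g - 1)) / (SS_within / (n - g)).
    The p-value is estimated by permuting labels with the given seed:
    p = (# permuted F >= observed F + 1) / (n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    if np.isnan(dm.values).any():
        raise ValueError("PERMANOVA requires a fully finite distance matrix")
    if isinstance(labels, Mapping):
        lab = [labels[s] for s in dm.ids]
    else:
        lab = list(labels)
        if len(lab) != dm.n:
            raise ValueError("labels length does not match matrix")
    _, groups = np.unique(lab, return_inverse=True)
    n, g = dm.n, int(groups.max()) + 1
    if g < 2:
        raise ValueError("need at least 2 groups")
    if g >= n:
        raise ValueError("each group needs at least 1 sample and g < n")
    d2 = dm.values**2

    def f_stat(gr: np.ndarray) -> float:
        ss_total, ss_within = _permanova_ss(d2, gr)
        ss_between = ss_total - ss_within
        if ss_within == 0.0:
            return np.inf
        return (ss_between / (g - 1)) / (ss_within / (n - g))

    ss_total, ss_within = _permanova_ss(d2, groups)
    r2 = 1.0 - ss_within / ss_total if ss_total > 0 else 0.0
    f_obs = f_stat(groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if f_stat(rng.permutation(groups)) >= f_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(
        R2=float(r2),
        pseudo_F=float(f_obs),
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
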