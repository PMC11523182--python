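"""Synthetic inputs with known ground truth.

Three generators, one per pipeline arm:

* host-structured strain alignments evolved under the K80 (Kimura
  two-parameter) substitution model on a star-within-star genealogy —
  one ancestor per host at divergence ``t_b`` from a common root, each
  strain at ``t_w`` from its host ancestor, so the expected K2P distance
  is ``2 t_w`` within a host and ``2 t_w + 2 t_b`` between hosts and the
  expected coherence score has the closed form ``t_b / (t_w + t_b)``;
* host-structured relative-abundance tables (log-normal baseline with
  host-signature taxa inflated by a chosen effect size);
* small MAG / Mash / ARG-hit fixtures whose records cover every branch
  and boundary of the screening and ARG filtering rules, with the
  intended outcome stored alongside each record.

All generators are fully deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceTable, AlignedStrainSet

__all__ = [
    "StrainSimParams",
    "evolve_sequence",
    "random_sequence",
    "simulate_strain_set",
    "simulate_abundance_table",
    "simulate_screening_fixtures",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _k80_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(P_same, P_transition, P_each_transversion) for branch length t.

    The K80 rate matrix is normalized so that t is the expected number of
    substitutions per site; kappa is the transition/transversion rate
    ratio (each of the two transversion targets has rate 1).
    """
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    beta_t = t / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e4 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * (alpha_t + beta_t))
    p_same = 0.25 + 0.25 * e4 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e4
    return float(p_same), float(p_ts), float(p_tv_each)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA sequence (the K80 stationary distribution)."""
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def evolve_sequence(
    seq: str, t: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve a sequence along a branch of length ``t`` under K80.

    Each site mutates independently using the model's closed-form
    transition probabilities. With codes A=0 C=1 G=2 T=3, the transition
    partner of c is c ^ 2 and the two transversion targets are c ^ 1 and
    c ^ 3.
    """
    p_same, p_ts, p_tv = _k80_probs(t, kappa)
    code = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    c = code[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    u = rng.random(c.size)
    out = np.where(
        u < p_same,
        c,
        np.where(
            u < p_same + p_ts,
            c ^ 2,
            np.where(u < p_same + p_ts + p_tv, c ^ 1, c ^ 3),
        ),
    ).astype(np.uint8)
    return _BASES[out].tobytes().decode("ascii")


@dataclass(frozen=True)
class StrainSimParams:
    """Configuration of the star-within-star strain simulator.

    t_w and t_b are branch lengths in expected substitutions per site:
    within-host (host ancestor -> strain) and root -> host ancestor.
    ``mixing`` is the fraction of strains whose host label is re-drawn
    uniformly at random after simulation (0 = perfectly host-structured,
    1 = labels carry no information).
    """

    seed: int
    hosts: tuple[str, ...] = ("cat", "dog", "human")
    n_per_host: int = 20
    length: int = 5000
    t_w: float = 0.01
    t_b: float = 0.09
    kappa: float = 2.0
    mixing: float = 0.0
    sgb_id: str = "SGB_sim"

    def __post_init__(self) -> None:
        if self.t_w < 0 or self.t_b < 0:
            raise ValueError("branch lengths must be nonnegative")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0 <= self.mixing <= 1:
            raise ValueError("mixing must lie in [0, 1]")
        if self.n_per_host < 1:
            raise ValueError("n_per_host must be >= 1")


def simulate_strain_set(
    params: StrainSimParams,
) -> tuple[AlignedStrainSet, pd.DataFrame]:
    """Simulate a host-labelled strain alignment plus its ground truth.

    Returns the alignment and a truth table with one row per strain:
    ``strain_id``, ``true_host`` (the ancestor it actually descends
    from), ``label`` (the possibly shuffled host label attached to the
    alignment) and ``relabelled``.
    """
    rng = np.random.default_rng(params.seed)
    root = random_sequence(params.length, rng)
    ancestors = {
        h: evolve_sequence(root, params.t_b, params.kappa, rng)
        for h in params.hosts
    }
    ids, seqs, true_hosts = [], [], []
    for h in params.hosts:
        for i in range(params.n_per_host):
            ids.append(f"{h}_{i + 1:03d}")
            seqs.append(
                evolve_sequence(ancestors[h], params.t_w, params.kappa, rng)
            )
            true_hosts.append(h)
    labels = list(true_hosts)
    n = len(ids)
    shuffled = rng.random(n) < params.mixing
    for i in np.flatnonzero(shuffled):
        labels[i] = params.hosts[rng.integers(len(params.hosts))]
    truth = pd.DataFrame(
        {
            "strain_id": ids,
            "true_host": true_hosts,
            "label": labels,
            "relabelled": shuffled,
        }
    )
    strains = AlignedStrainSet(
        strain_ids=tuple(ids),
        sequences=tuple(seqs),
        host_of=dict(zip(ids, labels)),
        sgb_id=params.sgb_id,
    )
    return strains, truth


def simulate_abundance_table(
    hosts: tuple[str, ...] = ("cat", "dog", "human"),
    n_per_host: int = 20,
    n_taxa: int = 100,
    n_signature_per_host: int = 5,
    effect: float = 5.0,
    seed: int = 0,
    sigma: float = 1.0,
) -> tuple[AbundanceTable, dict[str, list[str]]]:
    """Host-structured relative-abundance table with known signature taxa.

    Baseline abundances are log-normal (per-taxon log-mean drawn once,
    per-sample noise sigma); each host gets ``n_signature_per_host``
    disjoint signature taxa whose abundance is multiplied by
    ``1 + effect`` in that host's samples. Rows are renormalized to sum
    to 1. Returns the table (host labels attached) and the host ->
    signature-taxa map.
    """
    if effect < 0:
        raise ValueError("effect must be nonnegative")
    if n_taxa < n_signature_per_host * len(hosts):
        raise ValueError("not enough taxa for the requested signatures")
    rng = np.random.default_rng(seed)
    taxa = [f"T{j + 1:04d}" for j in range(n_taxa)]
    base_log_mean = rng.normal(0.0, 1.0, size=n_taxa)
    signature = {
        h: taxa[i * n_signature_per_host : (i + 1) * n_signature_per_host]
        for i, h in enumerate(hosts)
    }
    rows, sample_ids, host_of = [], [], {}
    for h in hosts:
        boost = np.ones(n_taxa)
        for tx in signature[h]:
            boost[taxa.index(tx)] = 1.0 + effect
        for i in range(n_per_host):
            sid = f"{h}_s{i + 1:03d}"
            raw = np.exp(base_log_mean + rng.normal(0.0, sigma, n_taxa)) * boost
            rows.append(raw / raw.sum())
            sample_ids.append(sid)
            host_of[sid] = h
    table = AbundanceTable(
        data=pd.DataFrame(rows, index=sample_ids, columns=taxa),
        host_of=host_of,
    )
    return table, signature


def simulate_screening_fixtures(seed: int = 0) -> dict[str, pd.DataFrame]:
    """Toy MAG / Mash / ARG-hit tables with planted expected outcomes.

    Handcrafted records pin every rule boundary (e.g. a MAG at exactly
    90% completeness, a Mash tie, an ARG hit at exactly 90/80/80);
    additional random records broaden coverage, with expectations derived
    from the rule definitions independently of the screening module.
    Returns ``{"mags": ..., "mash": ..., "arg_hits": ...}``.
    """
    rng = np.random.default_rng(seed)

    mag_rows = [
        # completeness, contamination, expected grade
        (95.0, 2.0, "high"),
        (60.0, 8.0, "medium"),
        (95.0, 7.0, "medium"),
        (90.0, 4.0, "medium"),  # boundary: high needs strictly > 90
        (91.0, 5.0, "medium"),  # boundary: high needs strictly < 5
        (50.0, 2.0, "low"),  # boundary: medium needs strictly > 50
        (80.0, 10.0, "low"),  # boundary: medium needs strictly < 10
        (40.0, 20.0, "low"),
        (100.0, 0.0, "high"),
    ]
    for _ in range(20):
        comp = float(np.round(rng.uniform(0, 100), 2))
        cont = float(np.round(rng.uniform(0, 20), 2))
        if comp > 90 and cont < 5:
            grade = "high"
        elif comp > 50 and cont < 10:
            grade = "medium"
        else:
            grade = "low"
        mag_rows.append((comp, cont, grade))
    mags = pd.DataFrame(
        [
            {
                "mag_id": f"MAG{i + 1:03d}",
                "completeness": c,
                "contamination": k,
                "expected_grade": g,
            }
            for i, (c, k, g) in enumerate(mag_rows)
        ]
    )

    mash_cases = [
        # {bin: distance}, expected bin, expected level
        ({"B1": 0.03, "B2": 0.40}, "B1", "SGB"),
        ({"B1": 0.12, "B2": 0.40}, "B1", "GGB"),
        ({"B1": 0.28, "B2": 0.40}, "B1", "FGB"),
        ({"B1": 0.35, "B2": 0.40}, "B1", "novel"),
        ({"B2": 0.03, "B1": 0.03}, "B1", "SGB"),  # tie -> smaller id
        ({"B1": 0.05, "B2": 0.40}, "B1", "GGB"),  # boundary: SGB < 0.05
        ({"B1": 0.15, "B2": 0.40}, "B1", "FGB"),  # boundary: GGB < 0.15
        ({"B1": 0.30, "B2": 0.40}, "B1", "novel"),  # boundary: FGB < 0.30
    ]
    for _ in range(10):
        d1 = float(np.round(rng.uniform(0, 0.6), 3))
        d2 = float(np.round(rng.uniform(0, 0.6), 3))
        best, d = ("B1", d1) if (d1, "B1") <= (d2, "B2") else ("B2", d2)
        level = (
            "SGB" if d < 0.05 else "GGB" if d < 0.15 else "FGB" if d < 0.30
            else "novel"
        )
        mash_cases.append(({"B1": d1, "B2": d2}, best, level))
    mash_rows = []
    for i, (dists, bin_id, level) in enumerate(mash_cases):
        for b, d in sorted(dists.items()):
            mash_rows.append(
                {
                    "mag_id": f"Q{i + 1:03d}",
                    "bin_id": b,
                    "distance": d,
                    "expected_bin": bin_id,
                    "expected_level": level,
                }
            )
    mash = pd.DataFrame(mash_rows)

    hit_rows = [
        # pident, qcov, scov, expected keep
        (92.0, 85.0, 85.0, True),
        (89.0, 95.0, 95.0, False),
        (95.0, 85.0, 70.0, False),  # mutual coverage means both
        (95.0, 70.0, 85.0, False),
        (90.0, 80.0, 80.0, True),  # boundaries inclusive ("at least")
        (89.99, 80.0, 80.0, False),
        (90.0, 79.99, 80.0, False),
        (100.0, 100.0, 100.0, True),
    ]
    for _ in range(20):
        pid = float(np.round(rng.uniform(70, 100), 2))
        qc = float(np.round(rng.uniform(50, 100), 2))
        sc = float(np.round(rng.uniform(50, 100), 2))
        hit_rows.append((pid, qc, sc, pid >= 90 and qc >= 80 and sc >= 80))
    arg_hits = pd.DataFrame(
        [
            {
                "qseqid": f"CARD{i + 1:03d}",
                "sseqid": f"UniRef90_G{i + 1:03d}",
                "pident": p,
                "qcovhsp": q,
                "scovhsp": s,
                "expected_keep": keep,
            }
            for i, (p, q, s, keep) in enumerate(hit_rows)
        ]
    )

    return {"mags": mags, "mash": mash, "arg_hits": arg_hits}
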