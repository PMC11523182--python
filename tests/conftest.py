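import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import strainniche as sn

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def small_metadata() -> sn.SampleTable:
    frame = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "host": ["cat", "dog", "dog", "human"],
            "study": ["A", "A", "B", "B"],
        }
    ).set_index("sample_id")
    return sn.SampleTable(frame)


def block_distance_matrix(host_scores: dict[str, float], n_per_host: int = 5):
    """Distance matrix whose host-specific coherence scores are exact.

    All between-host distances are 1 and all within-host distances for
    host h are 1 - score_h, so median(B) = 1, median(W) = 1 - score_h and
    host_score returns score_h exactly.
    """
    hosts = list(host_scores)
    ids, labels = [], {}
    for h in hosts:
        for i in range(n_per_host):
            sid = f"{h}{i}"
            ids.append(sid)
            labels[sid] = h
    n = len(ids)
    values = np.ones((n, n))
    for a in range(n):
        for b in range(n):
            ha, hb = labels[ids[a]], labels[ids[b]]
            if ha == hb:
                values[a, b] = 1.0 - host_scores[ha]
    np.fill_diagonal(values, 0.0)
    return sn.DistanceMatrix(tuple(ids), values), labels


@pytest.fixture(scope="session")
def structured_coherence_runs() -> list[float]:
    """Mean coherence per seed for well-separated host lineages.

    20 replicates at the standard simulation conditions (3 hosts, 20
    strains each, 5000 sites, t_w = 0.01, t_b = 0.09, no mixing); the
    expected score is t_b / (t_w + t_b) = 0.9.
    """
    scores = []
    for seed in range(20):
        params = sn.StrainSimParams(seed=seed)
        strains, _ = sn.simulate_strain_set(params)
        dm = sn.distance_matrix(strains)
        scores.append(sn.coherence_score(dm, strains.host_of).mean_score)
    return scores


@pytest.fixture(scope="session")
def mixed_coherence_runs() -> dict[str, list[float]]:
    """Mean coherence for label-free data: fully mixed and t_b = 0."""
    out = {"mixed": [], "flat": []}
    for seed in range(5):
        params = sn.StrainSimParams(seed=100 + seed, mixing=1.0)
        strains, _ = sn.simulate_strain_set(params)
        dm = sn.distance_matrix(strains)
        out["mixed"].append(sn.coherence_score(dm, strains.host_of).mean_score)
        params = sn.StrainSimParams(seed=200 + seed, t_b=0.0)
        strains, _ = sn.simulate_strain_set(params)
        dm = sn.distance_matrix(strains)
        out["flat"].append(sn.coherence_score(dm, strains.host_of).mean_score)
    return out


@pytest.fixture(scope="session")
def null_permanova_pvalues() -> np.ndarray:
    """PERMANOVA p-values under a true null: 200 seeded simulations of
    host-label-free abundance tables (12 samples, 199 permutations)."""
    pvals = []
    for seed in range(200):
        table, _ = sn.simulate_abundance_table(
            hosts=("cat", "dog"),
            n_per_host=6,
            n_taxa=30,
            n_signature_per_host=0,
            effect=0.0,
            seed=seed,
        )
        dm = sn.bray_curtis(table)
        res = sn.permanova(dm, table.host_of, n_permutations=199, seed=seed)
        pvals.append(res.p)
    return np.asarray(pvals)
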