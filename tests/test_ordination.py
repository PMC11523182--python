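import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

import strainniche as sn


def make_table(values, hosts=None, prefix="s"):
    ids = [f"{prefix}{i}" for i in range(len(values))]
    data = pd.DataFrame(
        values, index=ids, columns=[f"t{j}" for j in range(len(values[0]))]
    )
    host_of = dict(zip(ids, hosts)) if hosts else {}
    return sn.AbundanceTable(data, host_of=host_of)


def brute_force_permanova_r2(d, groups):
    """Independent sum-of-squares computation, direct from definitions."""
    n = len(groups)
    ss_total = sum(
        d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
    ) / n
    ss_within = 0.0
    for g in set(groups):
        idx = [i for i in range(n) if groups[i] == g]
        ss_within += sum(
            d[i, j] ** 2
            for a, i in enumerate(idx)
            for j in idx[a + 1 :]
        ) / len(idx)
    return 1 - ss_within / ss_total


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        table = make_table([[0.5, 0.5], [0.5, 0.5]])
        dm = sn.bray_curtis(table)
        assert dm.values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        table = make_table([[1.0, 0.0], [0.0, 1.0]])
        assert sn.bray_curtis(table).values[0, 1] == 1.0

    def test_hand_computed_value(self):
        table = make_table([[0.6, 0.4, 0.0], [0.2, 0.4, 0.4]])
        assert sn.bray_curtis(table).values[0, 1] == pytest.approx(0.4)

    def test_all_zero_sample_rejected(self):
        table = make_table([[0.5, 0.5], [0.0, 0.0]])
        with pytest.raises(ValueError, match="all-zero"):
            sn.bray_curtis(table)

    def test_range_and_symmetry_on_random_tables(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(0, 1, size=(10, 15))
        raw /= raw.sum(axis=1, keepdims=True)
        dm = sn.bray_curtis(make_table(raw))
        assert ((dm.values >= 0) & (dm.values <= 1)).all()
        np.testing.assert_allclose(dm.values, dm.values.T)


class TestPCoA:
    def test_collinear_points_recovered(self):
        # three points on a line at 0, 1, 2
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = sn.pcoa(sn.DistanceMatrix(("a", "b", "c"), d))
        assert res.eigenvalues.size == 1  # second axis is numerically zero
        axis = res.scores[:, 0]
        gaps = np.abs(np.diff(np.sort(axis)))
        np.testing.assert_allclose(gaps, [1.0, 1.0], atol=1e-8)

    def test_all_zero_distances(self):
        d = np.zeros((4, 4))
        res = sn.pcoa(sn.DistanceMatrix(tuple("abcd"), d))
        assert res.eigenvalues.size == 0
        assert res.scores.shape == (4, 0)

    def test_euclidean_input_reconstructed(self):
        """Scores of a Euclidean-embeddable matrix reproduce it exactly."""
        rng = np.random.default_rng(8)
        points = rng.normal(size=(7, 3))
        d = squareform(pdist(points))
        ids = tuple(f"p{i}" for i in range(7))
        res = sn.pcoa(sn.DistanceMatrix(ids, d))
        recon = squareform(pdist(res.scores))
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_eigenvalue_sum_equals_gower_trace(self):
        rng = np.random.default_rng(8)
        points = rng.normal(size=(6, 4))
        d = squareform(pdist(points))
        res = sn.pcoa(sn.DistanceMatrix(tuple("abcdef"), d))
        n = 6
        centered = np.eye(n) - np.full((n, n), 1 / n)
        gower = -0.5 * centered @ (d**2) @ centered
        assert res.eigenvalues.sum() == pytest.approx(np.trace(gower), abs=1e-8)

    def test_matches_skbio_eigenvalues(self):
        rng = np.random.default_rng(15)
        raw = rng.uniform(0, 1, size=(9, 12))
        raw /= raw.sum(axis=1, keepdims=True)
        table = make_table(raw)
        dm = sn.bray_curtis(table)
        ours = sn.pcoa(dm)
        ref = skbio_pcoa(SkbioDM(dm.values, ids=list(dm.ids)))
        ref_pos = np.array(
            [e for e in ref.eigvals if e > 1e-10 * max(ref.eigvals)]
        )
        np.testing.assert_allclose(
            ours.eigenvalues, ref_pos[: ours.eigenvalues.size], atol=1e-8
        )

    def test_too_many_axes_warns(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="fewer"):
            res = sn.pcoa(sn.DistanceMatrix(("a", "b", "c"), d), k=3)
        assert res.scores.shape[1] < 3


class TestFrequencyCorrect:
    def test_divides_by_group_size(self):
        res = sn.OrdinationResult(
            sample_ids=("c1",),
            eigenvalues=np.array([1.0]),
            scores=np.array([[7.34]]),
        )
        corrected = sn.frequency_correct(
            res, {"c1": "cat"}, group_sizes={"cat": 367}
        )
        assert corrected.scores[0, 0] == pytest.approx(0.02)
        assert corrected.corrected

    def test_groups_of_one_are_identity(self):
        res = sn.OrdinationResult(
            sample_ids=("a", "b"),
            eigenvalues=np.array([1.0]),
            scores=np.array([[1.5], [-2.5]]),
        )
        out = sn.frequency_correct(res, {"a": "x", "b": "y"})
        np.testing.assert_array_equal(out.scores, res.scores)

    def test_double_correction_guarded(self):
        res = sn.OrdinationResult(
            sample_ids=("a",),
            eigenvalues=np.array([1.0]),
            scores=np.array([[1.0]]),
            corrected=True,
        )
        with pytest.raises(ValueError, match="already"):
            sn.frequency_correct(res, {"a": "x"})

    def test_preserves_within_group_rank_order(self):
        rng = np.random.default_rng(2)
        ids = tuple(f"s{i}" for i in range(12))
        groups = {s: ("cat" if i < 8 else "dog") for i, s in enumerate(ids)}
        scores = rng.normal(size=(12, 2))
        res = sn.OrdinationResult(ids, np.ones(2), scores)
        out = sn.frequency_correct(res, groups)
        for g in ("cat", "dog"):
            idx = [i for i, s in enumerate(ids) if groups[s] == g]
            before = np.argsort(scores[idx, 0])
            after = np.argsort(out.scores[idx, 0])
            np.testing.assert_array_equal(before, after)


class TestFeaturePositions:
    def test_single_sample_taxon_sits_on_that_sample(self):
        table = make_table([[0.0, 1.0], [1.0, 0.0]])
        res = sn.pcoa(sn.bray_curtis(table))
        pos = sn.feature_positions(res, table, taxa=["t0"])
        np.testing.assert_allclose(
            pos.loc["t0"].to_numpy(), res.scores[1], atol=1e-12
        )

    def test_equal_weights_give_midpoint(self):
        table = make_table([[0.5, 0.5], [0.5, 0.5], [0.0, 1.0]], prefix="q")
        res = sn.OrdinationResult(
            sample_ids=("q0", "q1", "q2"),
            eigenvalues=np.array([1.0]),
            scores=np.array([[1.0], [3.0], [10.0]]),
        )
        sub = sn.AbundanceTable(
            pd.DataFrame(
                {"tx": [0.3, 0.3, 0.0]}, index=["q0", "q1", "q2"]
            )
        )
        pos = sn.feature_positions(res, sub)
        assert pos.loc["tx", "PC1"] == pytest.approx(2.0)

    def test_hand_computed_weighted_mean(self):
        res = sn.OrdinationResult(
            sample_ids=("a", "b", "c"),
            eigenvalues=np.array([1.0]),
            scores=np.array([[1.0], [2.0], [4.0]]),
        )
        table = sn.AbundanceTable(
            pd.DataFrame({"tx": [0.5, 0.3, 0.2]}, index=["a", "b", "c"])
        )
        pos = sn.feature_positions(res, table)
        expected = (0.5 * 1 + 0.3 * 2 + 0.2 * 4) / 1.0
        assert pos.loc["tx", "PC1"] == pytest.approx(expected)

    def test_zero_abundance_taxon_undefined(self):
        res = sn.OrdinationResult(
            sample_ids=("a", "b"),
            eigenvalues=np.array([1.0]),
            scores=np.array([[1.0], [2.0]]),
        )
        table = sn.AbundanceTable(
            pd.DataFrame({"tx": [0.0, 0.0], "ty": [0.5, 0.5]}, index=["a", "b"])
        )
        pos = sn.feature_positions(res, table)
        assert np.isnan(pos.loc["tx", "PC1"])


class TestPermanova:
    def test_perfect_separation_r2_one(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        dm = sn.DistanceMatrix(tuple("abcd"), d)
        res = sn.permanova(dm, ["g1", "g1", "g2", "g2"], 99, seed=0)
        assert res.R2 == pytest.approx(1.0)

    def test_all_equal_distances_p_one(self):
        d = np.ones((6, 6)) - np.eye(6)
        dm = sn.DistanceMatrix(tuple("abcdef"), d)
        res = sn.permanova(dm, ["x", "x", "x", "y", "y", "y"], 99, seed=1)
        assert res.p == 1.0

    def test_r2_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        dm = sn.DistanceMatrix(tuple(f"s{i}" for i in range(8)), d)
        groups = ["a", "a", "a", "b", "b", "c", "c", "c"]
        res = sn.permanova(dm, groups, 99, seed=2)
        expected = brute_force_permanova_r2(d, groups)
        assert res.R2 == pytest.approx(expected, abs=1e-10)

    def test_pseudo_f_matches_skbio(self):
        rng = np.random.default_rng(22)
        pts = rng.normal(size=(10, 4))
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(10)]
        groups = ["a"] * 5 + ["b"] * 5
        res = sn.permanova(sn.DistanceMatrix(tuple(ids), d), groups, 99, seed=3)
        ref = skbio_permanova(SkbioDM(d, ids=ids), grouping=groups,
                              permutations=99)
        assert res.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_single_group_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = sn.DistanceMatrix(tuple("abcd"), d)
        with pytest.raises(ValueError, match="2 groups"):
            sn.permanova(dm, ["g", "g", "g", "g"], 99, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(30)
        pts = rng.normal(size=(9, 3))
        d = squareform(pdist(pts))
        dm = sn.DistanceMatrix(tuple(f"s{i}" for i in range(9)), d)
        groups = ["a"] * 4 + ["b"] * 5
        r1 = sn.permanova(dm, groups, 199, seed=42)
        r2 = sn.permanova(dm, groups, 199, seed=42)
        assert r1 == r2

    def test_null_pvalues_uniform(self, null_permanova_pvalues):
        """Under a true null the permutation p-values are uniform."""
        from scipy.stats import kstest

        stat = kstest(null_permanova_pvalues, "uniform")
        assert stat.pvalue > 0.01
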