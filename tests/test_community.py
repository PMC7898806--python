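"""Diversity indices, Bray-Curtis, PCoA, dispersion, PERMANOVA, ANOVA/Tukey."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from loticom import (
    TaxaTable,
    bonferroni,
    bray_curtis,
    distance_to_centroid,
    pcoa,
    permanova,
    pielou,
    shannon,
    whittaker_beta,
)
from loticom.community import anova_tukey
from loticom.core import DistanceMatrix

from conftest import random_table


def _euclidean_dm(points: np.ndarray) -> DistanceMatrix:
    ids = [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([1.0] * 7, np.log(7)),           # S equal abundances -> ln S
            ([5.0, 0.0, 0.0], 0.0),           # single taxon -> 0
            ([1.0, 2.0, 3.0], 1.0114042647073),  # direct-summation oracle
        ],
    )
    def test_shannon_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-12)

    def test_shannon_rejects_empty(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    def test_shannon_log2_flag(self):
        assert shannon([1, 1, 1, 1], base=2) == pytest.approx(2.0)

    def test_pielou_uniform_is_one(self):
        assert pielou([3.0] * 9) == pytest.approx(1.0)

    def test_pielou_direct_value_and_scale_invariance(self):
        expected = shannon([0.9, 0.1]) / np.log(2)
        assert pielou([0.9, 0.1]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.468996, abs=1e-6)
        assert pielou([9.0, 1.0]) == pytest.approx(pielou([90.0, 10.0]), abs=1e-12)

    def test_pielou_single_taxon_is_error(self):
        with pytest.raises(ValueError):
            pielou([4.0, 0.0])


class TestWhittaker:
    def test_identical_samples_zero(self):
        t = TaxaTable(pd.DataFrame({"s1": [1.0, 2.0], "s2": [5.0, 1.0]},
                                   index=["a", "b"]))
        assert whittaker_beta(t) == pytest.approx(0.0)

    def test_disjoint_equal_sets(self):
        t = TaxaTable(pd.DataFrame({"s1": [1.0, 1.0, 0, 0], "s2": [0, 0, 1.0, 1.0]},
                                   index=list("abcd")))
        assert whittaker_beta(t) == pytest.approx(1.0)

    def test_nonnegative_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            table, _ = random_table(rng)
            assert whittaker_beta(table) >= 0

    def test_zero_richness_sample_is_error(self):
        t = TaxaTable(pd.DataFrame({"s1": [1.0], "s2": [0.0]}, index=["a"]))
        with pytest.raises(ValueError, match="s2"):
            whittaker_beta(t)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = TaxaTable(pd.DataFrame(
            {"same1": [2.0, 2.0, 0], "same2": [4.0, 4.0, 0], "other": [0, 0, 9.0]},
            index=list("abc")))
        dm = bray_curtis(t)
        assert dm["same1", "same2"] == pytest.approx(0.0)  # identical profiles
        assert dm["same1", "other"] == pytest.approx(1.0)  # disjoint

    def test_direct_evaluation(self):
        t = TaxaTable(pd.DataFrame({"s1": [10.0, 0.0], "s2": [5.0, 5.0]},
                                   index=["a", "b"]))
        assert bray_curtis(t)["s1", "s2"] == pytest.approx(0.5, abs=1e-12)

    def test_bounded_and_zero_iff_identical_profiles(self):
        rng = np.random.default_rng(11)
        table, _ = random_table(rng, n_taxa=10, n_samples=6)
        dm = bray_curtis(table)
        assert ((dm.data >= 0) & (dm.data <= 1 + 1e-12)).all()
        rel = table.relative_abundance()
        for i, a in enumerate(table.sample_ids):
            for b in table.sample_ids[i + 1:]:
                oracle = np.abs(rel[a] - rel[b]).sum() / (rel[a] + rel[b]).sum()
                assert dm[a, b] == pytest.approx(oracle, abs=1e-12)
                same = np.array_equal(rel[a].to_numpy(), rel[b].to_numpy())
                assert (dm[a, b] == 0) == same


class TestPcoa:
    def test_collinear_points_give_single_axis(self):
        x = np.array([[0.0], [1.0], [3.0], [7.0]])
        res = pcoa(_euclidean_dm(x))
        assert (res.eigenvalues > 1e-9).sum() == 1
        axis = res.coords[:, 0]
        gaps = np.abs(np.diff(np.sort(axis)))
        assert np.allclose(np.sort(gaps), np.sort(np.diff(x[:, 0])), atol=1e-9)

    def test_equilateral_triangle_two_equal_eigenvalues(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        res = pcoa(_euclidean_dm(pts))
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], abs=1e-9)

    def test_eigenvalue_sum_equals_centred_trace(self):
        rng = np.random.default_rng(0)
        table, _ = random_table(rng)
        dm = bray_curtis(table)
        res = pcoa(dm)
        d = dm.data
        a = -0.5 * d**2
        centered = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
        assert res.eigenvalues.sum() == pytest.approx(np.trace(centered), abs=1e-9)

    def test_asymmetric_input_rejected(self):
        m = np.array([[0, 1.0, 2], [1.5, 0, 1], [2, 1, 0]])
        fake = type("FakeDM", (), {"data": m, "ids": ["a", "b", "c"]})()
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(fake)


class TestDispersion:
    def test_two_identical_samples_zero(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [3.0, 0.0], [4.0, 0.0]])
        res = distance_to_centroid(_euclidean_dm(pts), ["g1", "g1", "g2", "g2"])
        assert res.distances.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res.distances.iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_pair_splits_distance_in_half(self):
        pts = np.array([[0.0], [5.0]])
        res = distance_to_centroid(_euclidean_dm(pts), ["g", "g"])
        assert np.allclose(res.distances, 2.5, atol=1e-9)

    def test_matches_euclidean_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 4))
        groups = ["a"] * 6 + ["b"] * 6
        res = distance_to_centroid(_euclidean_dm(pts), groups)
        for g in ("a", "b"):
            members = pts[[i for i, x in enumerate(groups) if x == g]]
            oracle = np.linalg.norm(members - members.mean(axis=0), axis=1)
            got = res.distances[[x == g for x in groups]].to_numpy()
            assert np.allclose(got, oracle, atol=1e-10)

    def test_equal_generative_dispersion_gives_similar_group_means(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, size=(40, 3))
        b = rng.normal(5, 1, size=(40, 3))  # different centroid, same spread
        res = distance_to_centroid(_euclidean_dm(np.vstack([a, b])),
                                   ["a"] * 40 + ["b"] * 40)
        da = res.distances[:40]
        db = res.distances[40:]
        se = np.sqrt(da.var() / 40 + db.var() / 40)
        assert abs(da.mean() - db.mean()) < 3 * se

    def test_singleton_group_is_error(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            distance_to_centroid(_euclidean_dm(pts), ["g1", "g1", "solo"])


class TestPermanova:
    def test_complete_separation_minimum_p(self):
        data = {f"a{i}": [10.0, 0.0] for i in range(7)}
        data |= {f"b{i}": [0.0, 10.0] for i in range(7)}
        dm = bray_curtis(TaxaTable(pd.DataFrame(data, index=["x", "y"])))
        res = permanova(dm, ["A"] * 7 + ["B"] * 7, permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.r_squared == pytest.approx(1.0)

    def test_p_floor_and_r2_range(self):
        rng = np.random.default_rng(1)
        table, meta = random_table(rng, n_taxa=15, n_samples=8)
        dm = bray_curtis(table)
        res = permanova(dm, ["g1"] * 4 + ["g2"] * 4, permutations=99, seed=2)
        assert res.p_value >= 1 / 100
        assert 0 <= res.r_squared <= 1

    def test_null_p_values_are_uniform(self):
        """Exchangeable data: permutation p-values ~ U(0,1) (KS at alpha=0.01)."""
        rng = np.random.default_rng(0)
        pvals = []
        for run in range(200):
            pts = rng.normal(size=(10, 3))
            dm = _euclidean_dm(pts)
            res = permanova(dm, ["g1"] * 5 + ["g2"] * 5, permutations=99,
                            seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        stat, p = scipy.stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_identical_everywhere_is_error(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.raises(ValueError):
            permanova(dm, ["g1", "g1", "g2", "g2"], permutations=9, seed=0)

    def test_more_permutations_refine_p_consistently(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 1, (6, 3)), rng.normal(0.8, 1, (6, 3))])
        dm = _euclidean_dm(pts)
        groups = ["a"] * 6 + ["b"] * 6
        p1 = permanova(dm, groups, permutations=999, seed=7).p_value
        p2 = permanova(dm, groups, permutations=1999, seed=7).p_value
        assert abs(p1 - p2) < 10 / 1000


class TestAnovaTukey:
    def test_equal_means_small_f_large_p(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, 30)
        res = anova_tukey(vals, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        assert res.p_value > 0.05
        assert (res.tukey["p_adj"] > 0.05).all()

    def test_two_groups_tukey_equals_anova(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.0, 1, 8)])
        res = anova_tukey(vals, ["a"] * 8 + ["b"] * 8)
        assert res.tukey["p_adj"].iloc[0] == pytest.approx(res.p_value, abs=1e-5)

    def test_studentized_range_tail_matches_monte_carlo(self):
        """scipy's q distribution vs direct simulation, within 3 SE."""
        k, df, crit, n = 4, 20, 3.2, 100_000
        rng = np.random.default_rng(12)
        means = rng.normal(size=(n, k))
        s = np.sqrt(rng.chisquare(df, size=n) / df)
        q = np.ptp(means, axis=1) / s
        mc = (q > crit).mean()
        se = np.sqrt(mc * (1 - mc) / n)
        exact = scipy.stats.studentized_range.sf(crit, k, df)
        assert abs(mc - exact) <= 3 * se

    def test_degenerate_variance_is_error(self):
        with pytest.raises(ValueError):
            anova_tukey([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])


class TestBonferroni:
    def test_direct_arithmetic(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.04]), [0.02, 0.08])

    def test_single_p_unchanged_and_clamped(self):
        assert bonferroni([0.3])[0] == pytest.approx(0.3)
        assert bonferroni([0.9, 1.0])[1] == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])
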