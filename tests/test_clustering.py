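"""Correlation, average linkage, threshold cut, and occupancy."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from synexpress.clustering import (
    ClusteringParams,
    average_linkage,
    correlation_matrix,
    correlation_to_distance,
    cut_at_correlation,
    occupancy,
    pearson_centered,
)
from synexpress.errors import ClusteringError

from conftest import brute_force_average_linkage


def random_distance_matrix(rng, n):
    x = rng.random((n, n))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestPearson:
    def test_positive_affine_image_is_one(self):
        assert pearson_centered([0, 1, 2, 3], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        assert pearson_centered([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_worked_value_against_formula(self):
        # direct evaluation: cov = 3.5, sqrt(var_x * var_y) = sqrt(23.75)
        r = pearson_centered([0, 3, 1, 2], [0, 2, 2, 3])
        assert r == pytest.approx(3.5 / np.sqrt(23.75), abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ClusteringError, match="zero-variance"):
            pearson_centered([1, 1, 1], [1, 2, 3])

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(9), rng.random(9)
        assert pearson_centered(x, y) == pytest.approx(pearson_centered(y, x), abs=0)


class TestCorrelationMatrix:
    def test_matches_pairwise_calls(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.random((10, 8)))
        corr = correlation_matrix(m)
        for i in range(10):
            for j in range(10):
                expect = 1.0 if i == j else pearson_centered(m.iloc[i], m.iloc[j])
                assert corr.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_identical_rows_give_unit_correlation(self):
        m = pd.DataFrame([[0, 1, 2], [0, 1, 2]], index=["a", "b"])
        assert correlation_matrix(m).loc["a", "b"] == pytest.approx(1.0)

    def test_constant_row_names_the_gene(self):
        m = pd.DataFrame([[1, 1, 1], [0, 1, 2]], index=["flat", "ok"])
        with pytest.raises(ClusteringError, match="flat"):
            correlation_matrix(m)


class TestAverageLinkage:
    def test_two_leaves(self):
        tree = average_linkage(np.array([[0.0, 0.4], [0.4, 0.0]]), ["a", "b"])
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(0.4)

    def test_three_leaves_forced_sequence(self):
        d = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        tree = average_linkage(d)
        assert (tree.merges[0, 0], tree.merges[0, 1]) == (0, 1)
        assert tree.merges[0, 2] == pytest.approx(0.1)
        assert tree.merges[1, 2] == pytest.approx(0.5)  # mean of 0.5, 0.5

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ClusteringError, match="asymmetric"):
            average_linkage(d)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 13))
            d = random_distance_matrix(rng, n)
            tree = average_linkage(d)
            oracle = brute_force_average_linkage(d)
            for got, exp in zip(tree.merges, oracle):
                assert (got[0], got[1]) == (exp[0], exp[1])
                assert got[2] == pytest.approx(exp[2], abs=1e-12)
                assert got[3] == exp[3]

    def test_heights_match_scipy(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(4, 15))
            d = random_distance_matrix(rng, n)
            tree = average_linkage(d)
            z = sch.linkage(squareform(d, checks=False), method="average")
            assert np.allclose(np.sort(tree.merges[:, 2]), np.sort(z[:, 2]), atol=1e-10)

    def test_heights_monotone_non_decreasing(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            d = random_distance_matrix(rng, 12)
            h = average_linkage(d).merges[:, 2]
            assert (np.diff(h) >= -1e-12).all()


def _cluster(matrix: pd.DataFrame, r_min=0.7, min_report_size=2):
    corr = correlation_matrix(matrix)
    tree = average_linkage(correlation_to_distance(corr), labels=list(matrix.index))
    return cut_at_correlation(
        tree, corr, ClusteringParams(r_min=r_min, min_report_size=min_report_size)
    )


class TestCut:
    def test_two_tight_anticorrelated_pairs(self):
        m = pd.DataFrame(
            [[0, 1, 2, 3], [0, 1, 2, 3], [3, 2, 1, 0], [3, 2, 1, 0]],
            index=["a", "b", "c", "d"],
            dtype=float,
        )
        cs = _cluster(m)
        assert sorted(sorted(v) for v in cs.clusters.values()) == [["a", "b"], ["c", "d"]]
        assert all(r == pytest.approx(1.0) for r in cs.mean_r.values())

    def test_all_identical_genes_form_one_cluster(self):
        m = pd.DataFrame([[0, 1, 2]] * 5, index=list("abcde"), dtype=float)
        # identical rows: correlation exactly 1 pairwise
        cs = _cluster(m)
        assert len(cs.clusters) == 1
        assert sorted(cs.clusters[1]) == list("abcde")

    def test_partition_property(self):
        rng = np.random.default_rng(21)
        m = pd.DataFrame(rng.random((20, 10)), index=[f"g{i}" for i in range(20)])
        cs = _cluster(m, r_min=0.3)
        seen = sorted(g for v in cs.clusters.values() for g in v) + sorted(cs.singletons)
        assert sorted(seen) == sorted(m.index)

    def test_raising_r_min_refines_partition(self):
        rng = np.random.default_rng(22)
        m = pd.DataFrame(rng.random((25, 8)), index=[f"g{i}" for i in range(25)])
        loose = _cluster(m, r_min=0.2, min_report_size=1)
        tight = _cluster(m, r_min=0.6, min_report_size=1)

        def community(cs):
            lab = {}
            for cid, members in cs.clusters.items():
                for g in members:
                    lab[g] = ("c", cid)
            for g in cs.singletons:
                lab[g] = ("s", g)
            return lab

        l_loose, l_tight = community(loose), community(tight)
        for a in m.index:
            for b in m.index:
                if a < b and l_tight[a] == l_tight[b]:
                    assert l_loose[a] == l_loose[b]

    def test_cluster_ids_ordered_by_size_then_member(self):
        m = pd.DataFrame(
            [[0, 1, 2]] * 3 + [[2, 1, 0]] * 2,
            index=["x1", "x2", "x3", "a1", "a2"],
            dtype=float,
        )
        cs = _cluster(m)
        assert sorted(cs.clusters[1]) == ["x1", "x2", "x3"]
        assert sorted(cs.clusters[2]) == ["a1", "a2"]

    def test_small_groups_go_to_singletons(self):
        m = pd.DataFrame(
            [[0, 1, 2], [0, 1, 2], [2, 1, 0]],
            index=["a", "b", "lone"],
            dtype=float,
        )
        cs = _cluster(m, min_report_size=2)
        assert cs.singletons == ["lone"]


class TestOccupancy:
    def test_counting_oracle(self):
        rng = np.random.default_rng(33)
        m = pd.DataFrame(
            rng.integers(0, 3, size=(12, 6)).astype(float),
            index=[f"g{i}" for i in range(12)],
            columns=[f"t{j}" for j in range(6)],
        )
        m += rng.random((12, 6)) * 1e-3 * (m > 0)  # jitter nonzeros only
        cs = _cluster(m, r_min=-0.9, min_report_size=2)
        occ = occupancy(cs, m)
        for cid, members in cs.clusters.items():
            for t in m.columns:
                expect = sum(m.loc[g, t] > 0 for g in members) / len(members)
                assert occ.loc[cid, t] == pytest.approx(expect)
        assert ((occ.to_numpy() >= 0) & (occ.to_numpy() <= 1)).all()

    def test_full_and_half_occupancy(self):
        m = pd.DataFrame(
            {"t1": [1.0] * 8, "t2": [1, 1, 1, 1, 0, 0, 0, 0], "t3": np.arange(8) * 1.0},
            index=[f"g{i}" for i in range(8)],
        )
        from synexpress.clustering import ClusterSet

        cs = ClusterSet(clusters={1: list(m.index)}, singletons=[], mean_r={1: 1.0})
        occ = occupancy(cs, m)
        assert occ.loc[1, "t1"] == pytest.approx(1.0)
        assert occ.loc[1, "t2"] == pytest.approx(0.5)

    def test_missing_gene_is_an_error(self):
        from synexpress.clustering import ClusterSet

        m = pd.DataFrame({"t": [1.0, 2.0]}, index=["a", "b"])
        cs = ClusterSet(clusters={1: ["a", "ghost"]}, singletons=[], mean_r={1: 1.0})
        with pytest.raises(ClusteringError, match="ghost"):
            occupancy(cs, m)


def test_newick_export_contains_all_leaves():
    d = np.array([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
    tree = average_linkage(d, ["a", "b", "c"])
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for leaf in ("a", "b", "c"):
        assert leaf in nwk
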