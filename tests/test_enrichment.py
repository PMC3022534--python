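"""Hypergeometric enrichment, bundle permutation, and calibration."""

import math

import numpy as np
import pytest

from synexpress.clustering import ClusteringParams, ClusterSet
from synexpress.enrichment import (
    FunctionalAnnotation,
    calibrate,
    enrich,
    hypergeom_upper,
    permute_bundles,
    propagate_functional,
    read_functional,
)
from synexpress.errors import EnrichmentError
from synexpress.ontology import AnatomyOntology, OntologyTerm

from conftest import hypergeom_enumeration, random_dag


class TestHypergeomUpper:
    def test_k_zero_is_one(self):
        assert hypergeom_upper(0, 5, 4, 10) == 1.0

    def test_worked_case(self):
        # enumeration over all C(10,5)=252 subsets gives 66 with overlap >= 3
        assert hypergeom_upper(3, 5, 4, 10) == pytest.approx(66 / 252, abs=1e-12)

    def test_forced_full_overlap(self):
        assert hypergeom_upper(4, 4, 4, 4) == pytest.approx(1.0)

    def test_bound_violations_rejected(self):
        for bad in [(5, 4, 6, 10), (1, 11, 2, 10), (1, 2, 11, 10), (-1, 2, 2, 10)]:
            with pytest.raises(EnrichmentError):
                hypergeom_upper(*bad)

    def test_matches_enumeration_small_universe(self):
        for N in (5, 8):
            for n in range(N + 1):
                for K in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert hypergeom_upper(k, n, K, N) == pytest.approx(
                            hypergeom_enumeration(k, n, K, N), abs=1e-12
                        )

    def test_monotone_non_increasing_in_k(self):
        ps = [hypergeom_upper(k, 6, 5, 12) for k in range(6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestPropagateFunctional:
    def test_dag_closure_adds_ancestors(self):
        onto = AnatomyOntology(
            [
                OntologyTerm("root", "root"),
                OntologyTerm("mid", "mid", frozenset({("root", "is_a")})),
                OntologyTerm("leaf", "leaf", frozenset({("mid", "is_a")})),
            ]
        )
        out = propagate_functional(
            [FunctionalAnnotation("g", "GO", "leaf")], {"GO": onto}
        )
        assert {(a.gene_id, a.term_id) for a in out} == {
            ("g", "leaf"),
            ("g", "mid"),
            ("g", "root"),
        }

    def test_flat_namespace_unchanged(self):
        anns = [FunctionalAnnotation("g", "cytoband", "1q21")]
        assert propagate_functional(anns) == anns

    def test_closure_matches_reachability_oracle(self):
        rng = np.random.default_rng(17)
        onto = random_dag(rng, 30)
        anns = [FunctionalAnnotation(f"g{i}", "GO", f"t{i}") for i in range(0, 30, 5)]
        out = propagate_functional(anns, {"GO": onto})
        for a in anns:
            expect = {a.term_id} | onto.ancestors(a.term_id)
            got = {x.term_id for x in out if x.gene_id == a.gene_id}
            assert got == expect


def _toy(universe_size=30, cluster_size=10):
    universe = [f"g{i:02d}" for i in range(universe_size)]
    clusters = ClusterSet(
        clusters={1: universe[:cluster_size]},
        singletons=universe[cluster_size:],
        mean_r={1: 0.9},
        params=ClusteringParams(min_enrich_size=10),
    )
    return universe, clusters


class TestEnrich:
    def test_counts_match_set_intersections(self):
        universe, clusters = _toy()
        anns = [FunctionalAnnotation(g, "NS", "termA") for g in universe[5:20]]
        anns += [FunctionalAnnotation(g, "NS", "termB") for g in universe[::3]]
        results = enrich(clusters, anns, universe)
        by_term = {r.term_id: r for r in results}
        a = by_term["termA"]
        assert (a.k, a.n, a.K, a.N) == (5, 10, 15, 30)
        b = by_term["termB"]
        assert b.k == len(set(universe[:10]) & set(universe[::3]))
        for r in results:
            assert r.p_hyper == pytest.approx(
                hypergeom_upper(r.k, r.n, r.K, r.N), abs=0
            )

    def test_minimal_attainable_p_for_perfect_overlap(self):
        universe = [f"g{i}" for i in range(100)]
        clusters = ClusterSet(
            clusters={1: universe[:10]}, singletons=universe[10:], mean_r={1: 1.0}
        )
        anns = [FunctionalAnnotation(g, "NS", "hit") for g in universe[:10]]
        (r,) = enrich(clusters, anns, universe)
        assert r.p_hyper == pytest.approx(1 / math.comb(100, 10), rel=1e-9)

    def test_small_clusters_not_tested(self):
        universe, _ = _toy()
        clusters = ClusterSet(
            clusters={1: universe[:9]}, singletons=universe[9:], mean_r={1: 0.9}
        )
        anns = [FunctionalAnnotation(g, "NS", "t") for g in universe]
        assert enrich(clusters, anns, universe) == []

    def test_empty_universe_rejected(self):
        clusters = ClusterSet(clusters={}, singletons=[], mean_r={})
        with pytest.raises(EnrichmentError, match="universe"):
            enrich(clusters, [], [])

    def test_sorted_by_namespace_cluster_pvalue(self):
        universe, clusters = _toy()
        anns = [FunctionalAnnotation(g, "B", "t1") for g in universe[:10]]
        anns += [FunctionalAnnotation(g, "A", "t2") for g in universe]
        results = enrich(clusters, anns, universe)
        keys = [(r.namespace, r.cluster_id, r.p_hyper) for r in results]
        assert keys == sorted(keys)


class TestPermuteBundles:
    def test_single_gene_universe_is_identity(self):
        anns = [FunctionalAnnotation("g", "NS", "t")]
        assert permute_bundles(anns, ["g"], seed=5) == anns

    def test_conserves_bundle_sizes_and_term_totals(self):
        universe = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(3)
        anns = [
            FunctionalAnnotation(g, "NS", f"t{rng.integers(5)}")
            for g in universe
            for _ in range(rng.integers(0, 4))
        ]
        out = permute_bundles(anns, universe, seed=11)

        def totals(lst):
            t: dict[str, int] = {}
            for a in lst:
                t[a.term_id] = t.get(a.term_id, 0) + 1
            return t

        def bundle_sizes(lst):
            b: dict[str, int] = {}
            for a in lst:
                b[a.gene_id] = b.get(a.gene_id, 0) + 1
            return sorted(b.values())

        assert totals(out) == totals(anns)
        assert bundle_sizes(out) == bundle_sizes(anns)

    def test_deterministic_given_seed(self):
        universe = [f"g{i}" for i in range(10)]
        anns = [FunctionalAnnotation(g, "NS", "t") for g in universe[:4]]
        assert permute_bundles(anns, universe, 7) == permute_bundles(anns, universe, 7)

    def test_outside_universe_rejected(self):
        with pytest.raises(EnrichmentError, match="outside"):
            permute_bundles([FunctionalAnnotation("ghost", "NS", "t")], ["g"], 1)


class TestCalibrate:
    def test_planted_signal_hits_estimator_floor(self):
        universe, clusters = _toy(universe_size=60, cluster_size=12)
        anns = [FunctionalAnnotation(g, "NS", "hit") for g in universe[:12]]
        (res,) = calibrate(
            clusters, anns, universe, thresholds=[0.001], n_perm=100, seed=2
        )
        assert res.perm_p == pytest.approx(1 / 101)
        assert res.observed_count == 1

    def test_zero_observed_count_gives_p_one(self):
        universe, clusters = _toy()
        anns = [FunctionalAnnotation(g, "NS", "t") for g in universe]  # K = N
        (res,) = calibrate(
            clusters, anns, universe, thresholds=[0.001], n_perm=50, seed=3
        )
        assert res.observed_count == 0
        assert res.perm_p == 1.0

    def test_fast_path_matches_enrich_on_permuted_bundles(self):
        universe, clusters = _toy(universe_size=40, cluster_size=10)
        rng = np.random.default_rng(9)
        anns = [
            FunctionalAnnotation(g, "NS", f"t{rng.integers(6)}")
            for g in universe
            for _ in range(rng.integers(0, 3))
        ]
        alpha = 0.2
        seed = 123
        n_perm = 10
        results = calibrate(
            clusters, anns, universe, thresholds=[alpha], n_perm=n_perm, seed=seed
        )
        # replay the permutation counts through the slow route
        counts = []
        for i in range(1, n_perm + 1):
            permuted = permute_bundles(anns, universe, seed + i)
            res = enrich(clusters, permuted, universe)
            counts.append(sum(1 for r in res if r.p_hyper <= alpha))
        obs = sum(
            1 for r in enrich(clusters, anns, universe) if r.p_hyper <= alpha
        )
        (cal,) = results
        assert cal.observed_count == obs
        assert cal.perm_mean == pytest.approx(np.mean(counts))
        assert cal.perm_max == max(counts)
        assert cal.perm_p == pytest.approx(
            (1 + sum(c >= obs for c in counts)) / (1 + n_perm)
        )

    def test_perm_p_never_zero_and_reproducible(self):
        universe, clusters = _toy()
        anns = [FunctionalAnnotation(g, "NS", "hit") for g in universe[:10]]
        a = calibrate(clusters, anns, universe, thresholds=[0.01], n_perm=30, seed=4)
        b = calibrate(clusters, anns, universe, thresholds=[0.01], n_perm=30, seed=4)
        assert a == b
        assert all(r.perm_p >= 1 / 31 for r in a)

    def test_super_uniform_under_nested_null(self):
        # draw null annotation sets, calibrate each at small n_perm, and check
        # P(perm_p <= alpha) <= alpha (with Monte-Carlo slack)
        universe, clusters = _toy(universe_size=40, cluster_size=10)
        alpha = 0.25
        hits = 0
        n_outer = 40
        rng = np.random.default_rng(100)
        for outer in range(n_outer):
            anns = [
                FunctionalAnnotation(g, "NS", f"t{rng.integers(4)}")
                for g in universe
                if rng.random() < 0.5
            ]
            (res,) = calibrate(
                clusters, anns, universe, thresholds=[0.1], n_perm=19,
                seed=int(rng.integers(1_000_000)),
            )
            if res.perm_p <= alpha:
                hits += 1
        # binomial(40, 0.25) 99th percentile is ~17
        assert hits <= 17

    def test_bad_thresholds_rejected(self):
        universe, clusters = _toy()
        with pytest.raises(EnrichmentError):
            calibrate(clusters, [], universe, thresholds=[1.5], n_perm=10, seed=1)


def test_read_functional_roundtrip(tmp_path):
    from synexpress.enrichment import write_functional

    anns = [FunctionalAnnotation("g1", "NS1", "t1"), FunctionalAnnotation("g2", "NS2", "t2")]
    p = tmp_path / "f.tsv"
    with open(p, "w") as fh:
        write_functional(anns, fh)
    with open(p) as fh:
        assert read_functional(fh) == anns
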