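"""Functional-term enrichment with permutation-calibrated significance.

Each sufficiently large synexpression cluster is tested for
over-representation of functional terms (GO-like DAG namespaces after
true-path ancestor closure, or flat namespaces such as protein domains,
phenotypes or cytogenetic bands) with the upper-tail hypergeometric
probability: for a cluster of n genes drawn from a universe of N genes
of which K carry a term, the p-value of observing an overlap of k is
P(X ≥ k) under sampling without replacement.

Because thousands of (cluster, term) tests are performed and functional
terms are strongly interdependent, per-test p-values are calibrated at
the threshold level: the number of tests passing each p-value threshold
in the observed data is compared with the same count in datasets where
whole per-gene annotation bundles are permuted across the gene universe.
Permuting bundles (rather than individual annotations) preserves all
within-gene term co-occurrence, so the null respects the annotation
interdependencies.  The permutation p-value uses the add-one estimator
(1 + #{permutations ≥ observed}) / (1 + n_perm), which is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .clustering import ClusterSet
from .errors import EnrichmentError
from .ontology import AnatomyOntology

__all__ = [
    "FunctionalAnnotation",
    "EnrichmentResult",
    "CalibrationResult",
    "DEFAULT_THRESHOLDS",
    "hypergeom_upper",
    "propagate_functional",
    "enrich",
    "permute_bundles",
    "calibrate",
    "read_functional",
    "write_functional",
]

DEFAULT_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class FunctionalAnnotation:
    gene_id: str
    namespace: str
    term_id: str


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric test for a (cluster, namespace, term) triple."""

    cluster_id: int
    namespace: str
    term_id: str
    k: int  # term-annotated genes in the cluster
    n: int  # cluster size
    K: int  # term-annotated genes in the universe
    N: int  # universe size
    p_hyper: float


@dataclass(frozen=True)
class CalibrationResult:
    """Permutation calibration of the sub-threshold test count.

    ``observed_count`` is the number of (cluster, term) tests in this
    namespace with p_hyper ≤ threshold on the real labels;
    ``perm_p = (1 + #{i: count_i ≥ observed_count}) / (1 + n_perm)``.
    """

    namespace: str
    threshold: float
    observed_count: int
    perm_mean: float
    perm_max: int
    perm_p: float
    n_perm: int
    seed: int


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X ≥ k).

    X counts term-carrying genes in a size-n subset drawn without
    replacement from N genes of which K carry the term.

    Raises
    ------
    EnrichmentError
        If the arguments violate 0 ≤ k ≤ min(n, K), k ≤ n ≤ N, K ≤ N.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise EnrichmentError(
            f"invalid hypergeometric arguments k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def propagate_functional(
    annotations: Iterable[FunctionalAnnotation],
    ontologies: Mapping[str, AnatomyOntology] | None = None,
) -> list[FunctionalAnnotation]:
    """Close DAG-namespace annotations under ancestors (true-path rule).

    Namespaces listed in ``ontologies`` are DAG-structured: each gene's
    term set is extended with all ancestors of its terms.  Other
    namespaces are flat and pass through unchanged.  Duplicate
    (gene, namespace, term) triples are removed; first-seen order is
    preserved.
    """
    ontologies = ontologies or {}
    seen: set[tuple[str, str, str]] = set()
    out: list[FunctionalAnnotation] = []

    def add(gene: str, ns: str, term: str) -> None:
        key = (gene, ns, term)
        if key not in seen:
            seen.add(key)
            out.append(FunctionalAnnotation(gene, ns, term))

    for a in annotations:
        add(a.gene_id, a.namespace, a.term_id)
        onto = ontologies.get(a.namespace)
        if onto is not None:
            if a.term_id not in onto:
                raise EnrichmentError(
                    f"annotation term {a.term_id!r} absent from the "
                    f"{a.namespace!r} ontology"
                )
            for anc in sorted(onto.ancestors(a.term_id)):
                add(a.gene_id, a.namespace, anc)
    return out


def _annotation_frame(
    annotations: Iterable[FunctionalAnnotation],
) -> pd.DataFrame:
    df = pd.DataFrame(
        [(a.gene_id, a.namespace, a.term_id) for a in annotations],
        columns=["gene_id", "namespace", "term_id"],
    )
    return df.drop_duplicates()


class _NamespaceTables:
    """Per-namespace boolean gene×term matrices aligned to the universe.

    Shared vectorised core for :func:`enrich` and :func:`calibrate`:
    with cluster membership M (clusters×genes) and annotation matrix A
    (genes×terms), the overlap counts are k = M @ A for every
    (cluster, term) pair at once.
    """

    def __init__(
        self,
        clusters: ClusterSet,
        annotations: Iterable[FunctionalAnnotation],
        universe: Sequence[str],
        min_enrich_size: int,
    ):
        self.universe = list(universe)
        if not self.universe:
            raise EnrichmentError("empty gene universe")
        if len(set(self.universe)) != len(self.universe):
            raise EnrichmentError("universe contains duplicate gene ids")
        self.N = len(self.universe)
        gene_pos = {g: i for i, g in enumerate(self.universe)}

        self.cluster_ids = [
            cid
            for cid, members in sorted(clusters.clusters.items())
            if len(members) >= min_enrich_size
        ]
        self.memb = np.zeros((len(self.cluster_ids), self.N), dtype=np.int64)
        for row, cid in enumerate(self.cluster_ids):
            for g in clusters.clusters[cid]:
                if g not in gene_pos:
                    raise EnrichmentError(
                        f"cluster {cid} gene {g!r} is outside the universe"
                    )
                self.memb[row, gene_pos[g]] = 1
        self.sizes = self.memb.sum(axis=1)

        df = _annotation_frame(annotations)
        outside = sorted(set(df["gene_id"]) - set(self.universe))
        df = df[df["gene_id"].isin(gene_pos)]
        self.outside_genes = outside
        self.tables: dict[str, tuple[list[str], np.ndarray]] = {}
        for ns, sub in df.groupby("namespace", sort=True):
            terms = sorted(sub["term_id"].unique())
            tpos = {t: j for j, t in enumerate(terms)}
            A = np.zeros((self.N, len(terms)), dtype=np.int64)
            A[
                [gene_pos[g] for g in sub["gene_id"]],
                [tpos[t] for t in sub["term_id"]],
            ] = 1
            self.tables[ns] = (terms, A)

    def counts(self, ns: str, gene_perm: np.ndarray | None = None) -> np.ndarray:
        terms, A = self.tables[ns]
        if gene_perm is not None:
            A = A[gene_perm]
        return self.memb @ A

    def pvalues(self, ns: str, k: np.ndarray) -> np.ndarray:
        _, A = self.tables[ns]
        K = A.sum(axis=0)
        n = self.sizes[:, None]
        p = hypergeom.sf(k - 1, self.N, K[None, :], n)
        p[k == 0] = 1.0
        return p


def enrich(
    clusters: ClusterSet,
    annotations: Iterable[FunctionalAnnotation],
    universe: Sequence[str],
    min_enrich_size: int | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment for every big-enough cluster and term.

    One result is emitted per (cluster with ≥ ``min_enrich_size`` genes,
    namespace, term with K ≥ 1 in the universe); annotations of genes
    outside the universe are ignored.  Results are sorted by (namespace,
    cluster_id, p_hyper).

    The universe defaults to — and is normally — the clustered gene set,
    since clusters are drawn from exactly that set.
    """
    if min_enrich_size is None:
        min_enrich_size = clusters.params.min_enrich_size
    tab = _NamespaceTables(clusters, annotations, universe, min_enrich_size)
    results: list[EnrichmentResult] = []
    for ns in tab.tables:
        terms, A = tab.tables[ns]
        K = A.sum(axis=0)
        k = tab.counts(ns)
        p = tab.pvalues(ns, k)
        for row, cid in enumerate(tab.cluster_ids):
            for col, term in enumerate(terms):
                if K[col] < 1:
                    continue
                results.append(
                    EnrichmentResult(
                        cluster_id=cid,
                        namespace=ns,
                        term_id=term,
                        k=int(k[row, col]),
                        n=int(tab.sizes[row]),
                        K=int(K[col]),
                        N=tab.N,
                        p_hyper=float(p[row, col]),
                    )
                )
    results.sort(key=lambda r: (r.namespace, r.cluster_id, r.p_hyper, r.term_id))
    return results


def permute_bundles(
    annotations: Iterable[FunctionalAnnotation],
    universe: Sequence[str],
    seed: int,
) -> list[FunctionalAnnotation]:
    """Reassign whole per-gene annotation bundles by a random permutation.

    A uniform permutation π of the universe is drawn from ``seed``; gene
    g receives the complete annotation bundle (all namespaces) of π(g).
    Bundles stay intact, so within-bundle term co-occurrence — the
    annotation interdependency structure — is preserved, and every
    per-term universe count K is conserved.

    Raises
    ------
    EnrichmentError
        If an annotation references a gene outside the universe.
    """
    universe = list(universe)
    annotations = list(annotations)
    outside = sorted({a.gene_id for a in annotations} - set(universe))
    if outside:
        raise EnrichmentError(f"annotations reference genes outside universe: {outside}")
    rng = np.random.default_rng(seed)
    pi = rng.permutation(len(universe))
    bundles: dict[str, list[FunctionalAnnotation]] = {g: [] for g in universe}
    for a in annotations:
        bundles[a.gene_id].append(a)
    out: list[FunctionalAnnotation] = []
    for i, g in enumerate(universe):
        donor = universe[pi[i]]
        for a in bundles[donor]:
            out.append(FunctionalAnnotation(g, a.namespace, a.term_id))
    return out


def calibrate(
    clusters: ClusterSet,
    annotations: Iterable[FunctionalAnnotation],
    universe: Sequence[str],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    n_perm: int = 10_000,
    seed: int = 0,
    min_enrich_size: int | None = None,
) -> list[CalibrationResult]:
    """Permutation calibration of sub-threshold test counts per namespace.

    For each namespace and threshold α, the observed number of tests
    with p_hyper ≤ α is compared with the same count in ``n_perm``
    bundle-permuted datasets (permutation i uses ``seed + i``, matching
    :func:`permute_bundles`); perm_p is the add-one proportion of
    permutations with a count at least as large.

    The per-permutation count is computed without re-evaluating any
    hypergeometric probability: since the permutation conserves every
    cluster size n and term total K, p ≤ α is equivalent to k ≥ k_min(α)
    for a precomputed critical overlap per (cluster, term, α).
    """
    thresholds = list(thresholds)
    if any(not (0.0 < a < 1.0) for a in thresholds):
        raise EnrichmentError("thresholds must lie strictly between 0 and 1")
    if n_perm < 1:
        raise EnrichmentError("n_perm must be >= 1")
    if min_enrich_size is None:
        min_enrich_size = clusters.params.min_enrich_size
    annotations = list(annotations)
    tab = _NamespaceTables(clusters, annotations, universe, min_enrich_size)
    if tab.outside_genes:
        raise EnrichmentError(
            f"annotations reference genes outside universe: {tab.outside_genes}"
        )

    # critical overlap per (cluster, term, alpha): smallest k with p <= alpha
    kmin: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    for ns in tab.tables:
        terms, A = tab.tables[ns]
        K = A.sum(axis=0)
        max_k = np.minimum(tab.sizes[:, None], K[None, :])
        # p(k) for k = 0..max over the whole grid in one vectorised call
        kk = np.arange(int(max_k.max(initial=0)) + 1)
        grid = hypergeom.sf(
            kk[None, None, :] - 1, tab.N, K[None, :, None], tab.sizes[:, None, None]
        )
        grid[..., 0] = 1.0
        crit = np.full((len(thresholds),) + max_k.shape, np.iinfo(np.int64).max)
        for ai, alpha in enumerate(thresholds):
            ok = grid <= alpha
            ok[kk[None, None, :] > max_k[..., None]] = False
            any_ok = ok.any(axis=2)
            first = ok.argmax(axis=2)
            crit[ai][any_ok] = first[any_ok]
        kmin[ns] = crit
        k_obs = tab.counts(ns)
        observed[ns] = np.array(
            [(k_obs >= crit[ai]).sum() for ai in range(len(thresholds))]
        )

    perm_counts = {ns: np.zeros((n_perm, len(thresholds)), dtype=np.int64) for ns in tab.tables}
    for i in range(n_perm):
        pi = np.random.default_rng(seed + 1 + i).permutation(tab.N)
        for ns in tab.tables:
            k = tab.counts(ns, gene_perm=pi)
            for ai in range(len(thresholds)):
                perm_counts[ns][i, ai] = (k >= kmin[ns][ai]).sum()

    results: list[CalibrationResult] = []
    for ns in tab.tables:
        for ai, alpha in enumerate(thresholds):
            counts_i = perm_counts[ns][:, ai]
            obs = int(observed[ns][ai])
            ge = int((counts_i >= obs).sum())
            results.append(
                CalibrationResult(
                    namespace=ns,
                    threshold=float(alpha),
                    observed_count=obs,
                    perm_mean=float(counts_i.mean()),
                    perm_max=int(counts_i.max()),
                    perm_p=(1 + ge) / (1 + n_perm),
                    n_perm=n_perm,
                    seed=seed,
                )
            )
    return results


def read_functional(stream) -> list[FunctionalAnnotation]:
    """Read a ``gene_id<TAB>namespace<TAB>term_id`` table (header required)."""
    import io as _io

    fh = _io.StringIO(stream) if isinstance(stream, str) else stream
    body = [
        (i + 1, ln.rstrip("\n"))
        for i, ln in enumerate(fh)
        if ln.strip() and not ln.startswith("#")
    ]
    if not body:
        raise EnrichmentError("functional table is empty (header row required)")
    header_no, header = body[0]
    if [c.strip() for c in header.split("\t")[:3]] != ["gene_id", "namespace", "term_id"]:
        raise EnrichmentError(
            f"line {header_no}: expected columns gene_id, namespace, term_id"
        )
    out = []
    for no, ln in body[1:]:
        fields = [f.strip() for f in ln.split("\t")]
        if len(fields) < 3 or not all(fields[:3]):
            raise EnrichmentError(f"line {no}: malformed row {ln!r}")
        out.append(FunctionalAnnotation(*fields[:3]))
    return out


def write_functional(annotations: Iterable[FunctionalAnnotation], fh) -> None:
    fh.write("gene_id\tnamespace\tterm_id\n")
    for a in annotations:
        fh.write(f"{a.gene_id}\t{a.namespace}\t{a.term_id}\n")
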