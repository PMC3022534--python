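"""Synexpression clustering: centred Pearson, average linkage, threshold cut.

Gene expression profiles (rows of the propagated gene×term matrix) are
compared with the centred Pearson correlation coefficient r, converted
to the dissimilarity d = 1 − r (anticorrelated genes are *not*
synexpressed, so the sign is kept), agglomerated with unweighted average
linkage (UPGMA-style: inter-cluster distance is the mean over all
cross-pairs), and cut into flat clusters at a correlation threshold:
a flat cluster is a maximal subtree all of whose internal merge heights
are ≤ 1 − r_min, which guarantees that every internal merge joined
subclusters whose mean cross-correlation was at least r_min.

The agglomeration uses the exact Lance–Williams update for average
linkage and a deterministic tie-break (smallest left node index, then
smallest right node index), so results are bit-reproducible across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ClusteringError

__all__ = [
    "ClusteringParams",
    "MergeTree",
    "ClusterSet",
    "pearson_centered",
    "correlation_matrix",
    "average_linkage",
    "cut_at_correlation",
    "occupancy",
]


@dataclass(frozen=True)
class ClusteringParams:
    """Thresholds governing the flat cut and downstream reporting.

    r_min : minimum Pearson correlation for co-membership (default 0.7).
    min_report_size : smallest cluster reported (default 2; smaller
        groups are listed as singletons).
    min_enrich_size : smallest cluster eligible for enrichment testing
        (default 10, to ensure sufficient annotation to carry out tests).
    """

    r_min: float = 0.7
    min_report_size: int = 2
    min_enrich_size: int = 10

    def __post_init__(self):
        if not (-1.0 < self.r_min < 1.0):
            raise ClusteringError(f"r_min must lie in (-1, 1), got {self.r_min}")
        if not (self.min_enrich_size >= self.min_report_size >= 1):
            raise ClusteringError(
                "need min_enrich_size >= min_report_size >= 1, got "
                f"{self.min_enrich_size} / {self.min_report_size}"
            )


@dataclass
class MergeTree:
    """Agglomeration result in scipy linkage convention.

    ``leaves`` are gene ids, numbered 0..n−1; merge i creates node n+i.
    ``merges`` is an (n−1, 4) array of (left node, right node, height,
    size), heights non-decreasing, in [0, 2] for d = 1 − r.
    """

    leaves: list[str]
    merges: np.ndarray

    def __post_init__(self):
        n = len(self.leaves)
        if self.merges.shape != (max(n - 1, 0), 4):
            raise ClusteringError(
                f"expected {n - 1} merges for {n} leaves, got {self.merges.shape}"
            )
        h = self.merges[:, 2]
        if len(h) and (np.diff(h) < -1e-9).any():
            raise ClusteringError("merge heights are not non-decreasing")

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences to parent."""
        n = len(self.leaves)
        heights = np.concatenate([np.zeros(n), self.merges[:, 2]])

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - heights[node]
            if node < n:
                return f"{self.leaves[node]}:{bl:.6g}"
            left, right = int(self.merges[node - n, 0]), int(self.merges[node - n, 1])
            h = heights[node]
            return f"({render(left, h)},{render(right, h)}):{bl:.6g}"

        root = 2 * n - 2
        if n == 1:
            return f"{self.leaves[0]}:0;"
        h = heights[root]
        left, right = int(self.merges[-1, 0]), int(self.merges[-1, 1])
        return f"({render(left, h)},{render(right, h)});"


@dataclass
class ClusterSet:
    """Flat clusters from a threshold cut.

    ``clusters`` maps cluster_id (1..k, decreasing size, ties by smallest
    member gene id) to its ordered member list; genes in groups smaller
    than ``min_report_size`` are ``singletons``.  ``mean_r`` records each
    cluster's mean pairwise correlation.
    """

    clusters: dict[int, list[str]]
    singletons: list[str]
    mean_r: dict[int, float]
    params: ClusteringParams = field(default_factory=ClusteringParams)

    @property
    def genes(self) -> list[str]:
        out = [g for members in self.clusters.values() for g in members]
        out.extend(self.singletons)
        return out

    def sizes(self) -> dict[int, int]:
        return {cid: len(m) for cid, m in self.clusters.items()}


def pearson_centered(x, y) -> float:
    """Centred Pearson correlation between two equal-length vectors.

    Raises
    ------
    ClusteringError
        On length mismatch, length < 2, or zero variance in either input
        (the caller is expected to filter such genes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ClusteringError("inputs must be equal-length 1-d vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise ClusteringError("zero-variance input vector")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs centred Pearson correlations between gene rows.

    Zero-variance rows are reported by gene id before any computation.
    The result has unit diagonal and is numerically symmetric.
    """
    values = matrix.to_numpy(dtype=float)
    flat = values.std(axis=1) == 0.0
    if flat.any():
        bad = list(matrix.index[flat])
        raise ClusteringError(f"zero-variance gene rows: {bad}")
    corr = np.corrcoef(values)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.index, columns=matrix.index)


def correlation_to_distance(corr: pd.DataFrame) -> np.ndarray:
    """d = 1 − r with an exactly zero diagonal."""
    d = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage(distances, labels: list[str] | None = None) -> MergeTree:
    """Agglomerate with unweighted average linkage.

    ``distances`` is a square symmetric matrix with zero diagonal
    (d = 1 − r).  Inter-cluster distance is the mean over all cross-pairs
    of leaves, maintained exactly via the Lance–Williams recurrence
    d(k, i∪j) = (|i|·d(k,i) + |j|·d(k,j)) / (|i|+|j|).  Ties are broken
    by the smallest (left node, right node) index pair, nodes numbered in
    creation order (leaves first).

    Raises
    ------
    ClusteringError
        If the matrix is not square, asymmetric beyond 1e−9, or has a
        nonzero diagonal.
    """
    if isinstance(distances, pd.DataFrame):
        if labels is None:
            labels = list(distances.index)
        distances = distances.to_numpy(dtype=float)
    D0 = np.asarray(distances, dtype=float)
    n = D0.shape[0]
    if D0.ndim != 2 or D0.shape != (n, n):
        raise ClusteringError("distance matrix must be square")
    if np.abs(D0 - D0.T).max(initial=0.0) > 1e-9:
        raise ClusteringError("distance matrix asymmetric beyond 1e-9")
    if n and np.abs(np.diag(D0)).max() > 1e-12:
        raise ClusteringError("distance matrix diagonal must be zero")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ClusteringError("label count does not match matrix size")

    total = 2 * n - 1
    # D indexed by node id; inactive rows masked with +inf
    D = np.full((total, total), np.inf)
    D[:n, :n] = D0
    np.fill_diagonal(D, np.inf)
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    merges = np.empty((n - 1, 4)) if n > 1 else np.empty((0, 4))

    for step in range(n - 1):
        sub = D[: n + step, : n + step].copy()
        sub[~active[: n + step], :] = np.inf
        sub[:, ~active[: n + step]] = np.inf
        # argmin on the row-major flattened matrix lands on the smallest
        # (left, right) node-id pair among ties
        flat = int(np.argmin(sub))
        i, j = divmod(flat, n + step)
        if i > j:
            i, j = j, i
        height = D[i, j]
        new = n + step
        si, sj = sizes[i], sizes[j]
        ids = np.where(active[:new])[0]
        ids = ids[(ids != i) & (ids != j)]
        D[new, ids] = (si * D[i, ids] + sj * D[j, ids]) / (si + sj)
        D[ids, new] = D[new, ids]
        sizes[new] = si + sj
        active[i] = active[j] = False
        active[new] = True
        merges[step] = (i, j, height, si + sj)

    return MergeTree(leaves=list(labels), merges=merges)


def cut_at_correlation(
    tree: MergeTree,
    correlations: pd.DataFrame,
    params: ClusteringParams | None = None,
) -> ClusterSet:
    """Cut the merge tree into flat clusters at r ≥ r_min.

    A flat cluster is the leaf set of a maximal subtree whose internal
    merge heights are all ≤ 1 − r_min.  Groups smaller than
    ``min_report_size`` go to the singleton list.  The correlation matrix
    (gene×gene, same labels as the tree leaves) supplies each cluster's
    mean pairwise correlation.
    """
    params = params or ClusteringParams()
    cutoff = 1.0 - params.r_min
    n = len(tree.leaves)
    m = tree.merges.shape[0]

    good = np.zeros(m, dtype=bool)
    for k in range(m):
        left, right, h, _ = tree.merges[k]
        kids_good = all(
            c < n or good[int(c) - n] for c in (left, right)
        )
        good[k] = kids_good and h <= cutoff

    # leaves under each internal node
    members: list[list[int]] = [[i] for i in range(n)] + [[] for _ in range(m)]
    for k in range(m):
        left, right = int(tree.merges[k, 0]), int(tree.merges[k, 1])
        members[n + k] = members[left] + members[right]

    parent = np.full(2 * n - 1 if n else 0, -1, dtype=int)
    for k in range(m):
        parent[int(tree.merges[k, 0])] = n + k
        parent[int(tree.merges[k, 1])] = n + k

    groups: list[list[str]] = []
    for k in range(m):
        node = n + k
        p = parent[node]
        if good[k] and (p < 0 or not good[p - n]):
            groups.append([tree.leaves[i] for i in members[node]])
    grouped = {g for grp in groups for g in grp}
    loose = [g for g in tree.leaves if g not in grouped]

    corr = correlations.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(tree.leaves)}
    if list(correlations.index) != tree.leaves:
        corr = correlations.loc[tree.leaves, tree.leaves].to_numpy(dtype=float)

    singletons = list(loose)
    kept = []
    for grp in groups:
        if len(grp) >= params.min_report_size:
            kept.append(grp)
        else:
            singletons.extend(grp)
    kept.sort(key=lambda grp: (-len(grp), min(grp)))

    clusters: dict[int, list[str]] = {}
    mean_r: dict[int, float] = {}
    for cid, grp in enumerate(kept, start=1):
        clusters[cid] = list(grp)
        idx = [pos[g] for g in grp]
        sub = corr[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        mean_r[cid] = float(sub[iu].mean()) if len(iu[0]) else 1.0
    singletons.sort()
    return ClusterSet(clusters=clusters, singletons=singletons, mean_r=mean_r, params=params)


def occupancy(clusters: ClusterSet, matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster, per-term expression occupancy.

    Cell (c, t) is the number of genes in cluster c expressed in term t
    (propagated value > 0) divided by the cluster size, i.e. a fraction
    in [0, 1].

    Raises
    ------
    ClusteringError
        If a cluster member is missing from the matrix rows.
    """
    missing = [
        g
        for members in clusters.clusters.values()
        for g in members
        if g not in matrix.index
    ]
    if missing:
        raise ClusteringError(f"cluster genes missing from matrix: {missing}")
    rows = {}
    expressed = matrix > 0
    for cid, members in clusters.clusters.items():
        rows[cid] = expressed.loc[members].mean(axis=0)
    occ = pd.DataFrame(rows).T
    occ.index.name = "cluster_id"
    occ.columns.name = "term_id"
    return occ.reindex(sorted(rows))
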