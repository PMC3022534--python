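"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately take the dumbest correct route (path
enumeration, cross-pair means recomputed from the original matrix,
subset enumeration) so they share no code path with the implementation
they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from synexpress.ontology import AnatomyOntology, OntologyTerm


# ---------------------------------------------------------------- ontologies
def chain_ontology() -> AnatomyOntology:
    """A > B > C (A the root)."""
    return AnatomyOntology(
        [
            OntologyTerm("A", "A", frozenset()),
            OntologyTerm("B", "B", frozenset({("A", "is_a")})),
            OntologyTerm("C", "C", frozenset({("B", "is_a")})),
        ]
    )


@pytest.fixture
def chain():
    return chain_ontology()


def random_dag(rng: np.random.Generator, n_terms: int, max_parents: int = 3) -> AnatomyOntology:
    """Random DAG: term i may take parents among terms < i (acyclic by construction)."""
    terms = [OntologyTerm("t0", "t0", frozenset())]
    for i in range(1, n_terms):
        k = int(rng.integers(0, max_parents + 1)) if i > 0 else 0
        k = min(k, i)
        parents = rng.choice(i, size=k, replace=False) if k else []
        links = frozenset(
            (f"t{p}", ("is_a", "part_of")[int(rng.integers(2))]) for p in parents
        )
        terms.append(OntologyTerm(f"t{i}", f"t{i}", links))
    return AnatomyOntology(terms)


# ------------------------------------------------------------------- oracles
def reachability_descendants(ontology: AnatomyOntology, term: str) -> set[str]:
    """Descendants by exhaustive path expansion over child links."""
    frontier = [term]
    seen: set[str] = set()
    while frontier:
        node = frontier.pop()
        for child in ontology.children(node):
            if child not in seen:
                seen.add(child)
                frontier.append(child)
    return seen


def descendant_max(ontology: AnatomyOntology, raw: dict[str, float], term: str) -> float:
    """max over {raw(term)} ∪ {raw(d) : d descendant of term}, absent = 0."""
    vals = [raw.get(term, 0.0)]
    vals += [raw.get(d, 0.0) for d in reachability_descendants(ontology, term)]
    return max(vals)


def brute_force_average_linkage(D0: np.ndarray):
    """O(n^3) agglomeration recomputing cross-pair means from the original
    matrix at every step; same node numbering and tie-break contract as the
    implementation, but none of its incremental machinery."""
    n = D0.shape[0]
    members = {i: [i] for i in range(n)}
    merges = []
    nxt = n
    while len(members) > 1:
        best = None
        for a, b in itertools.combinations(sorted(members), 2):
            d = float(
                np.mean([D0[i, j] for i in members[a] for j in members[b]])
            )
            if best is None or d < best[0] - 1e-15 or (
                abs(d - best[0]) <= 1e-15 and (a, b) < (best[1], best[2])
            ):
                best = (d, a, b)
        d, a, b = best
        members[nxt] = members.pop(a) + members.pop(b)
        merges.append((a, b, d, len(members[nxt])))
        nxt += 1
    return merges


def hypergeom_enumeration(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by enumerating all size-n subsets of an N-gene universe
    in which genes 0..K-1 carry the term."""
    marked = set(range(K))
    hits = 0
    total = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(subset)) >= k:
            hits += 1
    return hits / total
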