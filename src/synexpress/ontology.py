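"""Anatomy-ontology handling and maximal upward propagation of expression.

The ontology is a rooted directed acyclic graph of anatomical terms (for
the mouse embryo, the EMAP-style anatomy hierarchy) connected by ``is_a``
and ``part_of`` parent links.  It serves as the coordinate system for the
per-gene expression vectors: a gene annotated as expressed in a structure
is implicitly expressed in every enclosing structure, which is made
explicit by *maximal propagation* — every term acquires the maximum
expression value found at the term itself or at any of its descendants.

Two interchangeable input carriers are supported: a small OBO-1.2 subset
(``[Term]`` stanzas with ``id``, ``name``, ``is_a``,
``relationship: part_of`` and ``is_obsolete`` tags) and a tab-separated
edge table with columns ``child_id``, ``parent_id``, ``relation``.

Both ``is_a`` and ``part_of`` transmit expression upward: inheritance of
properties between levels of an anatomical hierarchy does not depend on
the relation flavour.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

from .errors import OntologyError

__all__ = [
    "OntologyTerm",
    "AnatomyOntology",
    "parse_obo",
    "parse_edge_table",
    "write_edge_table",
    "propagate_max",
]

RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class OntologyTerm:
    """A single anatomical term.

    Parameters
    ----------
    term_id
        Opaque identifier, unique within its ontology.
    name
        Human-readable label; defaults to the identifier.
    parent_links
        Frozen set of ``(parent_term_id, relation)`` pairs with relation
        in ``{"is_a", "part_of"}``.
    """

    term_id: str
    name: str
    parent_links: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @property
    def parent_ids(self) -> frozenset[str]:
        return frozenset(p for p, _ in self.parent_links)


class AnatomyOntology:
    """A validated DAG of :class:`OntologyTerm`.

    Construction checks that every parent link resolves and that the
    parent graph is acyclic; structural oddities that are legal but
    suspicious (no roots, i.e. an empty ontology) are reported by
    :meth:`validate` rather than raised.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {}
        for t in terms:
            if t.term_id in self.terms:
                raise OntologyError(f"duplicate term id: {t.term_id!r}")
            self.terms[t.term_id] = t
        # graph edges run parent -> child
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for parent_id, relation in t.parent_links:
                if parent_id not in self.terms:
                    raise OntologyError(
                        f"term {t.term_id!r} references undeclared parent {parent_id!r}"
                    )
                if relation not in RELATIONS:
                    raise OntologyError(
                        f"term {t.term_id!r}: unknown relation {relation!r}"
                    )
                g.add_edge(parent_id, t.term_id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology parent graph contains a cycle: {cycle}")
        self._g = g
        self.roots: frozenset[str] = frozenset(
            tid for tid, t in self.terms.items() if not t.parent_links
        )

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __iter__(self):
        return iter(self.terms)

    def validate(self) -> list[str]:
        """Return a list of soft-invariant violations (empty if clean)."""
        violations: list[str] = []
        if not self.roots:
            violations.append("ontology has no root terms")
        return violations

    def _check_term(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise OntologyError(f"unknown term: {term_id!r}")

    def children(self, term_id: str) -> set[str]:
        self._check_term(term_id)
        return set(self._g.successors(term_id))

    def parents(self, term_id: str) -> set[str]:
        self._check_term(term_id)
        return set(self._g.predecessors(term_id))

    def descendants(self, term_id: str) -> set[str]:
        """Transitive closure over child links, excluding the term itself."""
        self._check_term(term_id)
        return set(nx.descendants(self._g, term_id))

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive closure over parent links, excluding the term itself."""
        self._check_term(term_id)
        return set(nx.ancestors(self._g, term_id))

    def leaves(self) -> list[str]:
        """Terms with no children, in insertion order."""
        return [tid for tid in self.terms if self._g.out_degree(tid) == 0]

    def topological_order(self) -> list[str]:
        """Parents-before-children order (deterministic for a given input)."""
        return list(nx.lexicographical_topological_sort(self._g))


def _as_text_stream(stream: IO[str] | str) -> IO[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_obo(stream: IO[str] | str) -> AnatomyOntology:
    """Parse an OBO-1.2 subset into an :class:`AnatomyOntology`.

    Recognised tags: ``id``, ``name``, ``is_a``, ``relationship``
    (``part_of`` only) and ``is_obsolete``.  Unknown tags are ignored,
    obsolete stanzas are skipped, and non-``[Term]`` stanzas (e.g.
    ``[Typedef]``) are ignored wholesale.

    Raises
    ------
    OntologyError
        On duplicate term ids, parent references to undeclared ids, or
        cycles in the parent graph.
    """
    fh = _as_text_stream(stream)
    stanzas: list[dict] = []
    current: dict | None = None
    in_term = False
    for rawline in fh:
        line = rawline.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if current is not None:
                stanzas.append(current)
                current = None
            in_term = line == "[Term]"
            if in_term:
                current = {"parents": []}
            continue
        if not in_term or current is None:
            continue
        if ":" not in line:
            continue
        tag, value = (s.strip() for s in line.split(":", 1))
        if tag == "id":
            current["id"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "is_a":
            current["parents"].append((value, "is_a"))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) >= 2 and parts[0] == "part_of":
                current["parents"].append((parts[1], "part_of"))
        elif tag == "is_obsolete" and value.lower() == "true":
            current["obsolete"] = True
    if current is not None:
        stanzas.append(current)

    terms: list[OntologyTerm] = []
    seen: set[str] = set()
    for st in stanzas:
        if st.get("obsolete"):
            continue
        tid = st.get("id")
        if tid is None:
            raise OntologyError("[Term] stanza without an id tag")
        if tid in seen:
            raise OntologyError(f"duplicate term id: {tid!r}")
        seen.add(tid)
        terms.append(
            OntologyTerm(
                term_id=tid,
                name=st.get("name", tid),
                parent_links=frozenset(st["parents"]),
            )
        )
    return AnatomyOntology(terms)


def parse_edge_table(stream: IO[str] | str) -> AnatomyOntology:
    """Parse a ``child_id<TAB>parent_id<TAB>relation`` table.

    The header row is required.  Terms are the union of all child and
    parent ids seen; names default to the ids.  Lines starting with ``#``
    are treated as comments.

    Raises
    ------
    OntologyError
        On a missing/wrong header, a malformed or bad-relation row
        (reported with its line number), or a cycle.
    """
    fh = _as_text_stream(stream)
    lines = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(fh)]
    body = [(no, ln) for no, ln in lines if ln.strip() and not ln.startswith("#")]
    if not body:
        raise OntologyError("edge table is empty (header row required)")
    header_no, header = body[0]
    cols = header.split("\t")
    expected = ["child_id", "parent_id", "relation"]
    if [c.strip() for c in cols[:3]] != expected:
        raise OntologyError(
            f"line {header_no}: expected header {expected}, got {cols[:3]}"
        )
    parent_links: dict[str, set[tuple[str, str]]] = {}
    order: list[str] = []

    def _touch(tid: str) -> None:
        if tid not in parent_links:
            parent_links[tid] = set()
            order.append(tid)

    for no, ln in body[1:]:
        fields = ln.split("\t")
        if len(fields) < 3 or any(not f.strip() for f in fields[:3]):
            raise OntologyError(f"line {no}: malformed row {ln!r}")
        child, parent, relation = (f.strip() for f in fields[:3])
        if relation not in RELATIONS:
            raise OntologyError(
                f"line {no}: relation must be one of {RELATIONS}, got {relation!r}"
            )
        _touch(parent)
        _touch(child)
        parent_links[child].add((parent, relation))
    terms = [
        OntologyTerm(tid, tid, frozenset(parent_links[tid])) for tid in order
    ]
    return AnatomyOntology(terms)


def write_edge_table(ontology: AnatomyOntology, fh: IO[str]) -> None:
    """Write the ontology as a child/parent/relation TSV (header included)."""
    fh.write("child_id\tparent_id\trelation\n")
    for tid, term in ontology.terms.items():
        for parent_id, relation in sorted(term.parent_links):
            fh.write(f"{tid}\t{parent_id}\t{relation}\n")


def propagate_max(
    ontology: AnatomyOntology, raw: Mapping[str, float]
) -> dict[str, float]:
    """Propagate expression values upward: parents acquire child values.

    For every term *t* in the output,

    ``out[t] = max({raw[t]} ∪ {raw[d] for d in descendants(t)})``

    with absent raw values defaulting to 0 ("not detected").  The output
    covers every term carrying a raw value plus all of their ancestors.
    Computed as a single children-before-parents sweep; the descendant-max
    contract is what the tests assert.

    Raises
    ------
    OntologyError
        If a raw key is not an ontology term, or a value is negative or
        non-finite.
    """
    for tid, value in raw.items():
        ontology._check_term(tid)
        v = float(value)
        if not (v >= 0.0) or v != v or v == float("inf"):
            raise OntologyError(
                f"raw value for {tid!r} must be finite and >= 0, got {value!r}"
            )
    domain: set[str] = set(raw)
    for tid in raw:
        domain |= ontology.ancestors(tid)

    out: dict[str, float] = {}
    for tid in reversed(ontology.topological_order()):
        if tid not in domain:
            continue
        best = float(raw.get(tid, 0.0))
        for child in ontology.children(tid):
            cv = out.get(child)
            if cv is None:
                # child outside the domain: it carries no raw signal and no
                # raw-signal descendants, so it contributes 0
                continue
            if cv > best:
                best = cv
        out[tid] = best
    return out
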