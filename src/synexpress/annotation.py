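"""Curated expression annotations and the propagated gene×term matrix.

Annotations record, per gene and anatomical term, an ordinal signal
strength (``not_detected`` < ``weak`` < ``moderate`` < ``strong``) and
optionally the pattern of the signal within the structure
(``homogeneous``, ``regional`` or ``single_cell``).  Genes fall into
three mutually exclusive expression categories:

* ``not_detected`` — no annotation above background anywhere;
* ``ubiquitous``   — homogeneous signal over the whole organism (a
  detected homogeneous annotation at a root term) or detected signal at
  nearly every leaf structure;
* ``regional``     — detected signal in a limited number of discrete
  locations.  Only regional genes enter synexpression clustering.

Strengths are encoded numerically (default 0/1/2/3).  Because gene
profiles are later compared with the centred Pearson correlation, which
is invariant to per-gene positive affine rescaling, any strictly
increasing encoding with 0 for not-detected yields the same clustering;
the ordinal integers are simply the canonical choice.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError
from .ontology import AnatomyOntology, propagate_max

__all__ = [
    "STRENGTH_LEVELS",
    "PATTERNS",
    "CATEGORIES",
    "AnnotationRecord",
    "StrengthEncoding",
    "read_annotations",
    "write_annotations",
    "classify_gene",
    "select_genes_regional",
    "build_matrix",
    "select_terms",
    "group_by_gene",
]

STRENGTH_LEVELS = ("not_detected", "weak", "moderate", "strong")
PATTERNS = ("homogeneous", "regional", "single_cell")
CATEGORIES = ("not_detected", "ubiquitous", "regional")

#: An ExpressionMatrix is a pandas DataFrame with gene rows and term columns.
ExpressionMatrix = pd.DataFrame


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    term_id: str
    strength: str
    pattern: str | None = None

    def __post_init__(self):
        if self.strength not in STRENGTH_LEVELS:
            raise AnnotationError(
                f"unknown strength {self.strength!r}; expected one of {STRENGTH_LEVELS}"
            )
        if self.pattern is not None and self.pattern not in PATTERNS:
            raise AnnotationError(
                f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}"
            )


@dataclass(frozen=True)
class StrengthEncoding:
    """Numeric encoding of the ordinal strength levels.

    Must be strictly increasing with ordinal level and map
    ``not_detected`` to 0.
    """

    values: Mapping[str, float] = field(
        default_factory=lambda: {
            "not_detected": 0.0,
            "weak": 1.0,
            "moderate": 2.0,
            "strong": 3.0,
        }
    )

    def __post_init__(self):
        missing = [s for s in STRENGTH_LEVELS if s not in self.values]
        if missing:
            raise AnnotationError(f"encoding missing levels: {missing}")
        vals = [float(self.values[s]) for s in STRENGTH_LEVELS]
        if vals[0] != 0.0:
            raise AnnotationError("not_detected must encode to 0")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise AnnotationError("encoding must be strictly increasing with level")

    def __call__(self, strength: str) -> float:
        return float(self.values[strength])


def read_annotations(
    stream: IO[str] | str,
    ontology: AnatomyOntology | None = None,
    strict: bool = False,
) -> list[AnnotationRecord]:
    """Read an annotation TSV (``gene_id  term_id  strength  [pattern]``).

    Strength and pattern tokens are case-insensitive.  If an ontology is
    supplied, records naming unknown terms trigger a warning and are kept,
    unless ``strict`` is set, in which case they are rejected.

    Raises
    ------
    AnnotationError
        On a missing header, malformed row, or unknown strength/pattern
        token — always with the offending line number.
    """
    fh = io.StringIO(stream) if isinstance(stream, str) else stream
    lines = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(fh)]
    body = [(no, ln) for no, ln in lines if ln.strip() and not ln.startswith("#")]
    if not body:
        raise AnnotationError("annotation table is empty (header row required)")
    header_no, header = body[0]
    cols = [c.strip() for c in header.split("\t")]
    if cols[:3] != ["gene_id", "term_id", "strength"]:
        raise AnnotationError(
            f"line {header_no}: expected columns gene_id, term_id, strength[, pattern]"
        )
    records: list[AnnotationRecord] = []
    for no, ln in body[1:]:
        fields = [f.strip() for f in ln.split("\t")]
        if len(fields) < 3 or not fields[0] or not fields[1] or not fields[2]:
            raise AnnotationError(f"line {no}: malformed row {ln!r}")
        gene_id, term_id = fields[0], fields[1]
        strength = fields[2].lower()
        if strength not in STRENGTH_LEVELS:
            raise AnnotationError(f"line {no}: unknown strength {fields[2]!r}")
        pattern: str | None = None
        if len(fields) > 3 and fields[3]:
            pattern = fields[3].lower()
            if pattern not in PATTERNS:
                raise AnnotationError(f"line {no}: unknown pattern {fields[3]!r}")
        if ontology is not None and term_id not in ontology:
            msg = f"line {no}: term {term_id!r} not in ontology"
            if strict:
                raise AnnotationError(msg)
            warnings.warn(msg, stacklevel=2)
        records.append(AnnotationRecord(gene_id, term_id, strength, pattern))
    return records


def write_annotations(records: Iterable[AnnotationRecord], fh: IO[str]) -> None:
    fh.write("gene_id\tterm_id\tstrength\tpattern\n")
    for r in records:
        fh.write(f"{r.gene_id}\t{r.term_id}\t{r.strength}\t{r.pattern or ''}\n")


def group_by_gene(
    records: Iterable[AnnotationRecord],
) -> dict[str, list[AnnotationRecord]]:
    """Group records per gene, preserving first-seen gene order."""
    groups: dict[str, list[AnnotationRecord]] = {}
    for r in records:
        groups.setdefault(r.gene_id, []).append(r)
    return groups


def classify_gene(
    records: Sequence[AnnotationRecord],
    ontology: AnatomyOntology,
    coverage_fraction: float = 0.9,
) -> str:
    """Assign one of the three expression categories to a gene.

    ``not_detected`` if no record rises above not-detected; ``ubiquitous``
    if a detected homogeneous annotation sits on a root term, or detected
    annotations cover at least ``coverage_fraction`` of the ontology's
    leaf terms; ``regional`` otherwise.
    """
    gene_ids = {r.gene_id for r in records}
    if len(gene_ids) > 1:
        raise AnnotationError(f"records span multiple genes: {sorted(gene_ids)}")
    detected = [r for r in records if r.strength != "not_detected"]
    if not detected:
        return "not_detected"
    roots = ontology.roots
    for r in detected:
        if r.pattern == "homogeneous" and r.term_id in roots:
            return "ubiquitous"
    leaves = ontology.leaves()
    if leaves:
        covered = {r.term_id for r in detected} & set(leaves)
        if len(covered) >= coverage_fraction * len(leaves):
            return "ubiquitous"
    return "regional"


def select_genes_regional(
    records: Iterable[AnnotationRecord],
    ontology: AnatomyOntology,
    coverage_fraction: float = 0.9,
) -> list[str]:
    """Gene ids classified regional, in first-seen input order."""
    return [
        gene
        for gene, recs in group_by_gene(records).items()
        if classify_gene(recs, ontology, coverage_fraction) == "regional"
    ]


def build_matrix(
    records: Iterable[AnnotationRecord],
    ontology: AnatomyOntology,
    encoding: StrengthEncoding | None = None,
    propagate: bool = True,
    term_policy: str | Sequence[str] = "all",
    genes: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Build the (optionally propagated) gene×term expression matrix.

    Duplicate ``(gene, term)`` records collapse by maximum encoded value,
    consistent with maximal propagation.  Rows are genes with at least one
    record (optionally restricted to ``genes``, e.g. the regional subset),
    columns the ontology terms under ``term_policy`` (see
    :func:`select_terms`).

    Raises
    ------
    AnnotationError
        If no gene survives ("empty matrix"), or a record names a term
        absent from the ontology.
    """
    encoding = encoding or StrengthEncoding()
    groups = group_by_gene(records)
    if genes is not None:
        wanted = set(genes)
        groups = {g: recs for g, recs in groups.items() if g in wanted}
    if not groups:
        raise AnnotationError("empty matrix: no gene has any annotation record")

    term_index = {tid: j for j, tid in enumerate(ontology.terms)}
    gene_list = list(groups)
    values = np.zeros((len(gene_list), len(term_index)))
    for i, gene in enumerate(gene_list):
        raw: dict[str, float] = {}
        for r in groups[gene]:
            if r.term_id not in term_index:
                raise AnnotationError(
                    f"gene {gene!r} annotated to unknown term {r.term_id!r}"
                )
            v = encoding(r.strength)
            if v > raw.get(r.term_id, -1.0):
                raw[r.term_id] = v
        if propagate:
            raw = propagate_max(ontology, raw)
        for tid, v in raw.items():
            values[i, term_index[tid]] = v

    matrix = pd.DataFrame(values, index=gene_list, columns=list(term_index))
    matrix.index.name = "gene_id"
    matrix.columns.name = "term_id"
    if isinstance(term_policy, str) and term_policy == "all":
        return matrix
    return select_terms(matrix, term_policy, ontology=ontology)


def select_terms(
    matrix: ExpressionMatrix,
    policy: str | Sequence[str] = "drop_empty",
    ontology: AnatomyOntology | None = None,
    min_genes: int = 1,
) -> ExpressionMatrix:
    """Restrict the matrix columns to an informative term subset.

    Policies
    --------
    ``all``
        Keep every column.
    ``drop_empty`` (default)
        Drop root terms (propagation makes them carry every signal, hence
        uninformative) and terms expressed in fewer than ``min_genes``
        genes.  Requires ``ontology`` to identify roots.
    ``leaves_only``
        Keep only the ontology's leaf terms.  Requires ``ontology``.
    explicit list of term ids
        Keep exactly those columns, in list order.

    Column order is otherwise preserved.
    """
    if not isinstance(policy, str):
        unknown = [t for t in policy if t not in matrix.columns]
        if unknown:
            raise AnnotationError(f"explicit term list names unknown terms: {unknown}")
        return matrix.loc[:, list(policy)]
    if policy == "all":
        return matrix.copy()
    if policy in ("drop_empty", "leaves_only") and ontology is None:
        raise AnnotationError(f"policy {policy!r} requires an ontology")
    if policy == "leaves_only":
        keep = [t for t in matrix.columns if t in set(ontology.leaves())]
        return matrix.loc[:, keep]
    if policy == "drop_empty":
        expressed = (matrix.values > 0).sum(axis=0)
        keep = [
            t
            for j, t in enumerate(matrix.columns)
            if t not in ontology.roots and expressed[j] >= min_genes
        ]
        return matrix.loc[:, keep]
    raise AnnotationError(f"unknown term policy {policy!r}")
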