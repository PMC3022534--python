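"""From an annotation table to expression categories and a gene x term matrix.

Each gene is classified as not_detected, ubiquitous (homogeneous signal at
the root, or near-total leaf coverage) or regional; only regional genes are
worth clustering, since a ubiquitous profile correlates with everything.
"""

import io

from synexpress import (
    build_matrix,
    classify_gene,
    parse_edge_table,
    read_annotations,
    select_genes_regional,
    select_terms,
)
from synexpress.annotation import group_by_gene

EDGES = "child_id\tparent_id\trelation\n" + "".join(
    f"leaf{i}\tembryo\tpart_of\n" for i in range(6)
)
ANNOTATIONS = """\
gene_id\tterm_id\tstrength\tpattern
shh_like\tleaf0\tstrong\tregional
shh_like\tleaf1\tmoderate\tregional
actb_like\tembryo\tmoderate\thomogeneous
silent_g\tleaf3\tnot_detected\t
"""

ontology = parse_edge_table(EDGES)
records = read_annotations(io.StringIO(ANNOTATIONS), ontology)

for gene, recs in group_by_gene(records).items():
    print(f"{gene:9s} -> {classify_gene(recs, ontology)}")

regional = select_genes_regional(records, ontology)
matrix = build_matrix(records, ontology, genes=regional)
matrix = select_terms(matrix, "drop_empty", ontology=ontology)
print("\npropagated matrix (regional genes, informative terms):")
print(matrix.to_string())
# values are the ordinal strength encoding (weak=1, moderate=2, strong=3)
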