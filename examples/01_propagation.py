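"""Maximal upward propagation of expression values on a small anatomy tree.

A gene detected in the metanephros is implicitly detected in the urinary
system and the whole embryo; propagation makes that explicit by giving
every term the maximum value found among its descendants.
"""

from synexpress import parse_edge_table, propagate_max

EDGES = """\
child_id\tparent_id\trelation
urinary_system\tembryo\tpart_of
metanephros\turinary_system\tpart_of
nephron\tmetanephros\tpart_of
brain\tembryo\tpart_of
"""

ontology = parse_edge_table(EDGES)
print(f"ontology: {len(ontology)} terms, roots = {sorted(ontology.roots)}")

# strong (3) signal in the nephron, moderate (2) in the brain
raw = {"nephron": 3.0, "brain": 2.0}
propagated = propagate_max(ontology, raw)
for term in sorted(propagated):
    print(f"  {term:16s} {propagated[term]:.0f}")
# every ancestor of the nephron now carries 3; the embryo root reports the
# organism-wide maximum, which is why roots are dropped before clustering
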