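# Methods

## Model and assumptions

The pipeline treats a curated expression atlas as a gene×term matrix
over an anatomy ontology. Three assumptions drive the design:

1. **Annotation is hierarchical and positive.** An annotation at a
   structure means the transcript was seen somewhere inside it, so
   expression values transmit *upward* only, by maximum. Both `is_a`
   and `part_of` links transmit values: inheritance between levels of an
   anatomical hierarchy does not depend on the relation flavour. The
   ontology may be a DAG (a term can have several parents); taking the
   maximum over all descendants makes path multiplicity harmless.
   Unannotated terms default to 0, the not-detected state.
2. **Only relative expression matters.** Strengths are ordinal
   (not_detected < weak < moderate < strong); the numeric encoding
   (default 0/1/2/3) is one admissible choice among many, because the
   centred Pearson correlation is invariant to per-gene positive affine
   rescaling. The encoding is configurable and the invariance is
   asserted by tests.
3. **Synexpression means positive co-expression.** The clustering
   dissimilarity is d = 1 − r, not 1 − |r|: anticorrelated genes are
   expressed in complementary structures and do not form a
   synexpression group.

## Clustering

Average linkage is computed with the exact Lance–Williams recurrence
for the unweighted (proportional) variant, so the inter-cluster
distance is always the mean over all cross-pairs of leaves. Ties in the
minimum search are broken by the smallest (left node, right node) index
pair, with nodes numbered in creation order; this makes merge order,
and therefore all downstream output, bit-reproducible across platforms.
Heights of average-linkage trees are monotone non-decreasing
(reducibility), which the `MergeTree` constructor asserts.

The flat cut at correlation threshold r_min keeps the maximal subtrees
whose internal merge heights are all ≤ 1 − r_min. This guarantees that
every merge inside a reported cluster joined subclusters whose mean
cross-correlation was at least r_min. Groups below `min_report_size`
(default 2) are reported as singletons; both the multi-gene cluster
count and the singleton count are emitted, since "number of clusters"
is ambiguous between the two conventions. Raising r_min can only refine
the partition (tested property).

Genes whose profile has zero variance over the selected terms (fully
silent genes, or genes expressed identically everywhere) carry no
correlation signal; they are reported and removed before the
correlation matrix is computed.

### Term selection

Propagation makes root terms carry every gene's maximum, so roots are
uninformative and the default `drop_empty` policy removes them along
with terms expressed in fewer than `min_genes` genes (default 1).
`leaves_only` and explicit term lists are available for sensitivity
analyses. Which "cut-down view" of a full anatomy tree feeds a given
published clustering is generally not recoverable, which is exactly why
the policy is configurable rather than hard-coded.

## Gene categories

`classify_gene` is a deterministic, exhaustive three-way rule:
not_detected if no record rises above not-detected; ubiquitous if a
detected homogeneous record sits on a root term **or** detected
annotations cover ≥ `coverage_fraction` (default 0.9) of the ontology's
leaf terms; regional otherwise. Real atlases classify by curator
judgment; the leaf-coverage threshold is an operationalisation and is
exposed in configuration for that reason.

## Enrichment and calibration

Per (cluster, namespace, term) the upper-tail hypergeometric
probability is computed (scipy's `hypergeom.sf`); clusters need
≥ `min_enrich_size` genes (default 10) for tests to be meaningful. The
universe is the clustered gene set: clusters are drawn from exactly
that set, and using a larger universe (e.g. a genome) would inflate
significance. DAG-structured namespaces are closed under ancestors
(true-path rule) before testing; flat namespaces pass through.

Calibration permutes whole per-gene annotation bundles across the
universe, preserving within-gene term co-occurrence, and compares the
observed number of tests passing each threshold with the permuted
counts. The permutation p-value uses the add-one estimator
(1 + b)/(1 + m): conservative, never zero, and super-uniform under the
null (tested by nesting calibration inside a null outer loop). Since a
bundle permutation conserves every cluster size n and term total K,
p ≤ α is equivalent to overlap k ≥ k_min(α) for a critical value
precomputed per (cluster, term, α); each permutation then only needs an
integer matrix product and a comparison, which keeps 10⁵-permutation
runs cheap. Default thresholds are {0.05, 0.01, 0.001, 0.0001};
`n_perm` defaults to 10,000 and is configurable upward.

## Synthetic generator

`SyntheticConfig` defaults define the reference benchmark: a complete
part_of tree of depth 4 and branching 3 (121 terms, 81 leaves); 10
modules × 12 genes with disjoint 6-leaf signatures, signature
annotation probability 0.9 and strengths moderate/strong at 0.3/0.7;
180 noise genes; background annotation probability 0.02 per
(gene, leaf) with strength weak; 5% per-annotation corruption (half
deletions, half strength redraws); two flat functional namespaces with
one planted term per module (module genes annotated at 0.9, others at
0.02).

Choices the generator makes beyond those numbers, fixed once:

- **Background functional terms.** 30 per namespace, annotating each
  gene at probability 0.05. Without them a dataset with no planted
  terms would carry no annotations at all and permutation calibration
  would be vacuous; with them the null calibration genuinely exercises
  the estimator. The rate puts typical term totals near K ≈ 15 of 300,
  large enough for occasional chance overlaps.
- **Noise-gene categories.** 5% of noise genes are emitted as
  root-homogeneous (ubiquitous) and 5% as silent, so the category
  classifier is exercised on all three outcomes in every run.
- **Leaf-only planting.** All expression annotations sit on leaves;
  internal-term signal exists only through propagation, so the ontology
  stage is on the critical path of every benchmark.

What the generator does *not* emulate: image- or section-level noise,
probe failure, curator disagreement, non-disjoint anatomical signatures
(an overlap knob exists but defaults to 0), correlated background, and
realistic ontology shape (real anatomies are unbalanced). Passing
recovery benchmarks here therefore demonstrates algorithmic
correctness and calibration, not performance on any particular real
atlas.

## Numerical choices

- Correlations are clipped to [−1, 1] and the matrix symmetrised
  ((C + Cᵀ)/2) to absorb floating-point asymmetry; asymmetry beyond
  1e−9 in a user-supplied distance matrix is an error, not repaired.
- Merge ties break on the smallest node-index pair (see above);
  cluster ids are assigned 1..k by decreasing size, ties by smallest
  member gene id.
- Duplicate (gene, term) annotation records collapse by maximum value,
  consistent with maximal propagation.
- The per-stage seeds of the pipeline derive from the master seed and
  the stage name (CRC32 offset, reduced mod 2³¹), so stages can be
  replayed independently and no two stages share a stream.
- Degenerate inputs: an empty ontology is a reported validation
  violation, not a crash; an empty cluster file is valid output with a
  header; a universe with one gene forces the identity permutation.

## Benchmark problem sizes

The shipped benchmarks use 300 genes (120 module + 180 noise), 121
terms, 20-seed
recovery sweeps, 1,000 permutations for the planted calibration and 50
null datasets × 199 permutations for the null rejection rate. These
sizes give stable Monte-Carlo estimates (recovery and power rates move
by at most one seed between master seeds) while keeping a full run
under a minute on one CPU.

## Known limitations

- The threshold-level calibration reports namespace-wide significance,
  not per-term corrected p-values; per-term values are reported raw.
- `classify_gene` uses raw (pre-propagation) leaf coverage; a gene
  annotated only at high internal terms counts as regional unless
  root-homogeneous, which may misclassify coarse annotations.
- The average-linkage implementation is O(n²) memory and O(n³) worst
  case time; it is comfortable to a few thousand genes but not intended
  for 10⁵-gene matrices.
- Pattern (homogeneous/regional/single-cell) is carried through parsing
  and classification but does not modulate the expression value; any
  weighting scheme would be speculative.
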