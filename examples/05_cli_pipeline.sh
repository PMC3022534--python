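#!/usr/bin/env bash
# Full shell pipeline: simulate a dataset, run every stage, score recovery.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

synexpress simulate --seed 1 --out "$workdir/sim"

cat > "$workdir/config.yaml" <<EOF
seed: 1
paths:
  ontology: $workdir/sim/ontology.tsv
  annotations: $workdir/sim/annotations.tsv
  functional: $workdir/sim/functional.tsv
  out_dir: $workdir/results
clustering:
  r_min: 0.7
enrichment:
  n_perm: 1000
EOF

synexpress run -c "$workdir/config.yaml"
synexpress score "$workdir/sim" "$workdir/results"
head -5 "$workdir/results/recovery.tsv"
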