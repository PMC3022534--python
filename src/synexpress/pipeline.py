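"""End-to-end pipeline: annotations → clusters → occupancy → enrichment.

This module wires the stages together behind a single configuration
object and writes the fixed TSV output formats.  Stages run in order:
read inputs → classify genes and keep the regional subset → build the
propagated gene×term matrix → restrict the term space → correlate and
cluster → occupancy → enrichment → permutation calibration.

All randomness flows from one master seed; per-stage seeds are derived
deterministically from the stage name so any stage can be replayed in
isolation.  Every output file starts with comment headers recording the
tool version, a digest of the configuration and the master seed, making
runs byte-reproducible and replayable from the log alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .annotation import (
    StrengthEncoding,
    build_matrix,
    classify_gene,
    group_by_gene,
    read_annotations,
    select_terms,
)
from .clustering import (
    ClusteringParams,
    ClusterSet,
    average_linkage,
    correlation_matrix,
    correlation_to_distance,
    cut_at_correlation,
    occupancy,
)
from .enrichment import (
    DEFAULT_THRESHOLDS,
    calibrate,
    enrich,
    read_functional,
)
from .errors import AnnotationError, ConfigError
from .ontology import AnatomyOntology, parse_edge_table, parse_obo

logger = logging.getLogger("synexpress")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "derive_seed"]


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Inputs, parameters and output location for one pipeline run."""

    ontology_path: str | Path
    annotations_path: str | Path
    functional_path: str | Path | None
    out_dir: str | Path
    seed: int
    encoding: StrengthEncoding = field(default_factory=StrengthEncoding)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    n_perm: int = 1000
    term_policy: str | Sequence[str] = "drop_empty"
    coverage_fraction: float = 0.9
    strict: bool = False

    def digest(self) -> str:
        # out_dir is where results land, not what they are
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, default=str, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    ontology: AnatomyOntology
    categories: dict[str, str]
    regional_genes: list[str]
    matrix: pd.DataFrame
    correlations: pd.DataFrame
    clusters: ClusterSet
    occupancy: pd.DataFrame
    enrichment: list
    calibration: list


def _load_ontology(path: Path) -> AnatomyOntology:
    text = path.read_text()
    if text.lstrip().startswith(("format-version", "[Term]", "[Typedef]")):
        return parse_obo(text)
    return parse_edge_table(text)


def _header(config: PipelineConfig) -> str:
    return (
        f"# synexpress {__version__}\n"
        f"# config_digest: {config.digest()}\n"
        f"# seed: {config.seed}\n"
    )


def _write_frame(path: Path, frame: pd.DataFrame, config: PipelineConfig, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        frame.to_csv(fh, sep="\t", index_label=index_label, float_format="%.4f")


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute all stages; optionally write the standard output files.

    Writes ``clusters.tsv``, ``occupancy.tsv``, ``enrichment.tsv``,
    ``calibration.tsv`` and ``run_log.txt`` under ``config.out_dir``.

    Raises
    ------
    SynexpressError subclasses
        From whichever stage fails, with the stage identified in the log;
        notably an explicit diagnostic when no gene is regional.
    """
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        logger.info(line)
        log_lines.append(line)

    ontology = _load_ontology(Path(config.ontology_path))
    log("read", f"ontology: {len(ontology)} terms, {len(ontology.roots)} roots")

    with open(config.annotations_path) as fh:
        records = read_annotations(fh, ontology, strict=config.strict)
    groups = group_by_gene(records)
    log("read", f"annotations: {len(records)} records, {len(groups)} genes")

    categories = {
        g: classify_gene(recs, ontology, config.coverage_fraction)
        for g, recs in groups.items()
    }
    regional = [g for g in groups if categories[g] == "regional"]
    counts = {c: sum(1 for v in categories.values() if v == c) for c in set(categories.values())}
    log("classify", f"categories: {counts}")
    if not regional:
        raise AnnotationError(
            "no gene classified regional: nothing to cluster "
            f"(categories seen: {counts})"
        )

    matrix = build_matrix(
        records, ontology, encoding=config.encoding, propagate=True, genes=regional
    )
    matrix = select_terms(matrix, config.term_policy, ontology=ontology)
    flat = matrix.std(axis=1) == 0.0
    if flat.any():
        dropped = list(matrix.index[flat])
        log("matrix", f"dropped {len(dropped)} zero-variance genes: {dropped[:5]}...")
        matrix = matrix.loc[~flat]
    log("matrix", f"{matrix.shape[0]} genes x {matrix.shape[1]} terms")

    corr = correlation_matrix(matrix)
    tree = average_linkage(correlation_to_distance(corr), labels=list(matrix.index))
    clusters = cut_at_correlation(tree, corr, config.clustering)
    log(
        "cluster",
        f"{len(clusters.clusters)} clusters (>= {config.clustering.min_report_size} genes), "
        f"{len(clusters.singletons)} singletons, r_min={config.clustering.r_min}",
    )

    occ = occupancy(clusters, matrix)

    enrichment_results: list = []
    calibration_results: list = []
    if config.functional_path is not None:
        with open(config.functional_path) as fh:
            functional = read_functional(fh)
        universe = list(matrix.index)
        functional = [a for a in functional if a.gene_id in set(universe)]
        enrichment_results = enrich(clusters, functional, universe)
        log("enrich", f"{len(enrichment_results)} tests over universe of {len(universe)}")
        calibration_results = calibrate(
            clusters,
            functional,
            universe,
            thresholds=config.thresholds,
            n_perm=config.n_perm,
            seed=derive_seed(config.seed, "calibrate"),
        )
        log("calibrate", f"n_perm={config.n_perm}, thresholds={list(config.thresholds)}")

    result = PipelineResult(
        ontology=ontology,
        categories=categories,
        regional_genes=regional,
        matrix=matrix,
        correlations=corr,
        clusters=clusters,
        occupancy=occ,
        enrichment=enrichment_results,
        calibration=calibration_results,
    )
    if write:
        _write_outputs(result, config, log_lines)
    return result


def _write_outputs(
    result: PipelineResult, config: PipelineConfig, log_lines: list[str]
) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(config)

    with open(out / "clusters.tsv", "w") as fh:
        fh.write(header)
        fh.write("cluster_id\tgene_id\tcluster_size\tmean_intra_r\n")
        for cid, members in result.clusters.clusters.items():
            for g in members:
                fh.write(
                    f"{cid}\t{g}\t{len(members)}\t{result.clusters.mean_r[cid]:.4f}\n"
                )
        for g in result.clusters.singletons:
            fh.write(f"0\t{g}\t1\t\n")

    _write_frame(out / "occupancy.tsv", result.occupancy, config, "cluster_id")

    with open(out / "enrichment.tsv", "w") as fh:
        fh.write(header)
        fh.write("cluster_id\tnamespace\tterm_id\tk\tn\tK\tN\tp_hyper\n")
        for r in result.enrichment:
            fh.write(
                f"{r.cluster_id}\t{r.namespace}\t{r.term_id}\t{r.k}\t{r.n}\t"
                f"{r.K}\t{r.N}\t{r.p_hyper:.6g}\n"
            )

    with open(out / "calibration.tsv", "w") as fh:
        fh.write(header)
        fh.write(
            "namespace\talpha\tobserved_count\tperm_mean\tperm_max\tperm_p\tn_perm\tseed\n"
        )
        for c in result.calibration:
            fh.write(
                f"{c.namespace}\t{c.threshold:g}\t{c.observed_count}\t"
                f"{c.perm_mean:.4f}\t{c.perm_max}\t{c.perm_p:.6g}\t{c.n_perm}\t{c.seed}\n"
            )

    with open(out / "run_log.txt", "w") as fh:
        fh.write(header)
        for line in log_lines:
            fh.write(line + "\n")
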