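"""End-to-end orchestration: QC -> selection -> annotation -> summaries -> networks.

Stages run in a fixed order; any stage failure aborts the run with the
stage name and cause, and no partial output directory is left behind
(outputs are staged and moved into place only on success).  Given
identical inputs and configuration, a rerun is byte-identical: tables are
written with fixed float formats and sorted orders, and the JSON manifest
carries no wall-clock timestamps (the run log does).
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (
    annotation_status,
    filter_by_zygosity,
    propagate_and_truncate,
    read_allele_report,
    study_counts,
    write_gene_annotations,
)
from .config import RunConfig
from .expression import (
    apply_qc_filters,
    concat_experiments,
    read_expression_matrix,
    read_qc_metrics,
)
from .network import build_phenotype_tree, export_network, pair_counts
from .ontology import read_obo
from .selection import (
    collapse_to_unique_genes,
    filter_protein_coding,
    intersect_required,
    per_gene_variance,
    read_probe_map,
    top_k_probes,
    write_uheg_table,
)
from .summarize import (
    annotation_histogram,
    housekeeping_overlap,
    percent,
    read_housekeeping_list,
    term_gene_count_table,
    write_term_table,
)

__all__ = ["run_pipeline", "PipelineError", "RunResult"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunResult:
    """In-memory products of a pipeline run."""

    config: RunConfig
    qc_kept: list[str] = field(default_factory=list)
    qc_excluded: dict[str, list[str]] = field(default_factory=dict)
    matrix: object = None
    intersection: set[str] = field(default_factory=set)
    coding_probes: set[str] = field(default_factory=set)
    uheg_records: list = field(default_factory=list)
    variance_table: object = None
    frac_var_below: float = 0.0
    records_filtered: list = field(default_factory=list)
    annotation: object = None
    status: dict[str, str] = field(default_factory=dict)
    studies: dict[str, int] = field(default_factory=dict)
    term_tables: dict[int, list] = field(default_factory=dict)
    histogram: object = None
    histogram_deep: object = None
    hk: dict[str, int] = field(default_factory=dict)
    pairs: list = field(default_factory=list)
    trees: dict[str, object] = field(default_factory=dict)
    ontology: object = None
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                logger.info("stage %s", name)
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - rewrap with stage context
                raise PipelineError(name, e) from e

        return wrapper

    return deco


@_stage("qc")
def _run_qc(result: RunResult) -> None:
    cfg = result.config
    metrics = read_qc_metrics(cfg.qc_metrics)
    qc = apply_qc_filters(metrics, cfg.qc_thresholds)
    result.qc_kept = qc.kept
    result.qc_excluded = qc.excluded
    logger.info("QC kept %d arrays, excluded %d", len(qc.kept), len(qc.excluded))

    matrices = [
        read_expression_matrix(p, cfg.sample_sheet) for p in cfg.expression_matrices
    ]
    full = concat_experiments(matrices)
    keep = [s for s in full.sample_ids if s in set(qc.kept)]
    result.matrix = full.subset_samples(keep)


@_stage("select")
def _run_select(result: RunResult) -> None:
    cfg = result.config
    matrix = result.matrix
    per_sample = {s: top_k_probes(matrix, s, cfg.k) for s in matrix.sample_ids}
    required = [
        s.sample_id for s in matrix.samples if s.required_for_intersection
    ]
    result.intersection = intersect_required(per_sample, required)
    probe_map = read_probe_map(cfg.probe_map)
    result.coding_probes = filter_protein_coding(
        result.intersection, probe_map, cfg.feature_type
    )
    result.uheg_records = collapse_to_unique_genes(
        result.coding_probes, probe_map, matrix
    )
    result.variance_table, result.frac_var_below = per_gene_variance(
        result.uheg_records, matrix, cfg.variance_threshold
    )


@_stage("annotate")
def _run_annotate(result: RunResult) -> None:
    cfg = result.config
    result.ontology = read_obo(cfg.ontology)
    records = read_allele_report(cfg.allele_report)
    filtered = filter_by_zygosity(records, cfg.zygosity_tokens)
    uheg_ids = {r.mgi_id for r in result.uheg_records}
    filtered = [r for r in filtered if r.mgi_id in uheg_ids]
    result.records_filtered = filtered
    result.annotation = propagate_and_truncate(
        filtered, result.ontology, cfg.max_level, cfg.excluded_term_names
    )
    result.status = annotation_status(sorted(uheg_ids), filtered, result.annotation)
    result.studies = study_counts(filtered)


@_stage("summarize")
def _run_summarize(result: RunResult) -> None:
    cfg = result.config
    total = len(result.uheg_records)
    result.term_tables = {
        level: term_gene_count_table(result.annotation, result.ontology, level, total)
        for level in range(1, cfg.max_level + 1)
    }
    result.histogram = annotation_histogram(result.annotation, result.studies)
    result.histogram_deep = annotation_histogram(
        result.annotation, result.studies, level=cfg.max_level
    )
    symbols = {r.mgi_id: r.gene_symbol for r in result.uheg_records}
    hk = read_housekeeping_list(cfg.housekeeping)
    result.hk = housekeeping_overlap(symbols, hk, result.status)


@_stage("cooccur")
def _run_cooccur(result: RunResult) -> None:
    result.pairs = pair_counts(result.annotation, result.config.pair_levels)


@_stage("trees")
def _run_trees(result: RunResult) -> None:
    cfg = result.config
    ont = result.ontology
    excluded_names = set(cfg.excluded_term_names)
    for top in sorted(ont.top_level_terms()):
        if ont.name(top) in excluded_names:
            continue
        result.trees[top] = build_phenotype_tree(
            ont, top, result.annotation, cfg.max_level
        )


def _build_manifest(result: RunResult) -> dict:
    cfg = result.config
    total = len(result.uheg_records)
    status_counts = {
        s: sum(1 for v in result.status.values() if v == s)
        for s in ("no_mutant", "mutant_no_abnormal", "abnormal")
    }
    n_with_mutant = status_counts["mutant_no_abnormal"] + status_counts["abnormal"]
    manifest = {
        "tool": "uhegpipe",
        "version": __version__,
        "config": cfg.to_dict(),
        "counts": {
            "samples_total": len(result.qc_kept) + len(result.qc_excluded),
            "samples_kept": len(result.qc_kept),
            "samples_excluded": len(result.qc_excluded),
            "probes_in_intersection": len(result.intersection),
            "probes_protein_coding": len(result.coding_probes),
            "n_uheg": total,
            "n_with_mutant": n_with_mutant,
            "pct_with_mutant": percent(n_with_mutant, total) if total else 0,
            "n_abnormal": status_counts["abnormal"],
            "pct_abnormal": percent(status_counts["abnormal"], total) if total else 0,
            "status": status_counts,
            "frac_variance_below_threshold": round(result.frac_var_below, 6),
            "terms_per_level": {
                str(lv): len(rows) for lv, rows in result.term_tables.items()
            },
            "housekeeping": result.hk,
            "n_term_pairs": len(result.pairs),
            "n_trees": len(result.trees),
            "n_trees_nonempty": sum(1 for t in result.trees.values() if t.nodes),
        },
    }
    return manifest


def _write_outputs(result: RunResult, outdir: Path) -> None:
    cfg = result.config
    write_uheg_table(result.uheg_records, outdir / "uheg.tsv")
    result.variance_table.assign(
        variance=result.variance_table["variance"].map("{:.6f}".format)
    ).to_csv(outdir / "gene_variance.tsv", sep="\t", index=False)

    symbols = {r.mgi_id: r.gene_symbol for r in result.uheg_records}
    write_gene_annotations(
        result.annotation, result.ontology, outdir / "gene_annotations.tsv", symbols
    )
    pd.DataFrame(
        [(g, symbols.get(g, ""), result.status[g], result.studies.get(g, 0))
         for g in sorted(result.status)],
        columns=["mgi_id", "gene_symbol", "status", "n_studies"],
    ).to_csv(outdir / "status.tsv", sep="\t", index=False)

    for level, rows in result.term_tables.items():
        write_term_table(rows, outdir / f"term_counts_level{level}.tsv")

    hist_rows = []
    for scope, hist in (("all_levels", result.histogram), (f"level{cfg.max_level}", result.histogram_deep)):
        for row in hist.terms_per_gene:
            hist_rows.append((scope, "terms_per_gene", row.label, row.gene_count))
        for row in hist.studies_per_gene:
            hist_rows.append((scope, "studies_per_gene", row.label, row.gene_count))
    pd.DataFrame(
        hist_rows, columns=["scope", "quantity", "bin", "gene_count"]
    ).to_csv(outdir / "histograms.tsv", sep="\t", index=False)

    export_network(result.pairs, "edgelist", outdir / "term_pairs.tsv")

    tree_dir = outdir / "trees"
    tree_dir.mkdir()
    for top, tree in result.trees.items():
        safe = top.replace(":", "_")
        export_network(tree, "sif", tree_dir / f"{safe}.sif")
        export_network(tree, "graphml", tree_dir / f"{safe}.graphml")

    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages and write the output directory atomically."""
    config.validate()
    result = RunResult(config=config)
    _run_qc(result)
    _run_select(result)
    _run_annotate(result)
    _run_summarize(result)
    _run_cooccur(result)
    _run_trees(result)
    result.manifest = _build_manifest(result)

    outdir = Path(config.output_dir)
    staging = outdir.parent / (outdir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        _write_outputs(result, staging)
    except Exception as e:  # noqa: BLE001
        shutil.rmtree(staging, ignore_errors=True)
        raise PipelineError("write", e) from e
    if outdir.exists():
        shutil.rmtree(outdir)
    staging.rename(outdir)
    return result
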