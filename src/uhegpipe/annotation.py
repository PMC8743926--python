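"""Phenotype annotation of genes from allele-level mutational-study records.

Each record in a phenotypic-allele report ties one mutant allele to its
gene, the zygosity class of the study, a PubMed-style study identifier and
the Mammalian Phenotype terms directly assigned to it.  The pipeline keeps
only records from the allowed zygosity classes (heterozygous and
homozygous studies by default), then builds per-gene term sets by
propagating every direct term to its is_a ancestors, truncating to
ontology levels 1..max_level (4 by default: annotation at the fourth level
below the root is specific enough for phenotype summarization while
keeping term counts manageable), and removing the "normal phenotype" and
"no phenotypic analysis" subtrees together with the root.

A gene's annotation status is tri-state: ``no_mutant`` (no retained
record), ``mutant_no_abnormal`` (records exist but the truncated abnormal
set is empty), or ``abnormal``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ontology import Ontology

__all__ = [
    "AlleleAnnotationRecord",
    "GeneTermAnnotation",
    "DEFAULT_ZYGOSITY_TOKENS",
    "DEFAULT_EXCLUDED_TERM_NAMES",
    "DEFAULT_MAX_LEVEL",
    "parse_allele_report",
    "read_allele_report",
    "filter_by_zygosity",
    "propagate_and_truncate",
    "annotation_status",
    "study_counts",
    "write_gene_annotations",
]

logger = logging.getLogger(__name__)

# MGI-style genotype class codes: hm homozygous, ht heterozygous.
DEFAULT_ZYGOSITY_TOKENS = ("hm", "ht")
DEFAULT_EXCLUDED_TERM_NAMES = ("normal phenotype", "no phenotypic analysis")
DEFAULT_MAX_LEVEL = 4

REPORT_COLUMNS = [
    "allele_id",
    "mgi_id",
    "gene_symbol",
    "zygosity_category",
    "study_id",
    "term_ids",
]


@dataclass(frozen=True)
class AlleleAnnotationRecord:
    allele_id: str
    mgi_id: str
    gene_symbol: str
    zygosity_category: str
    study_id: str  # may be empty
    term_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.mgi_id:
            raise ValueError(f"allele {self.allele_id!r} has empty MGI ID")


@dataclass
class GeneTermAnnotation:
    """Per-gene deduplicated (term, level) sets after propagation/truncation.

    ``genes`` maps MGI ID -> set of (term_id, level); levels all lie in
    1..max_level, no excluded-subtree term or root is ever present.
    ``dropped_terms`` counts direct term IDs that did not resolve in the
    supplied ontology (version drift) and were skipped.
    """

    genes: dict[str, set[tuple[str, int]]]
    max_level: int
    dropped_terms: int = 0

    def terms_of(self, mgi_id: str) -> set[tuple[str, int]]:
        return self.genes.get(mgi_id, set())


def parse_allele_report(stream) -> list[AlleleAnnotationRecord]:
    """Parse a phenotypic-allele report TSV.

    Columns: allele_id, mgi_id, gene_symbol, zygosity_category, study_id,
    term_ids (comma-delimited MP IDs within the cell; empty cell means the
    mutant was generated but nothing was annotated).
    """
    df = pd.read_csv(stream, sep="\t", dtype=str).fillna("")
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"allele report missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        terms = frozenset(t.strip() for t in r.term_ids.split(",") if t.strip())
        out.append(
            AlleleAnnotationRecord(
                allele_id=r.allele_id,
                mgi_id=r.mgi_id,
                gene_symbol=r.gene_symbol,
                zygosity_category=r.zygosity_category,
                study_id=r.study_id,
                term_ids=terms,
            )
        )
    return out


def read_allele_report(path: str | Path) -> list[AlleleAnnotationRecord]:
    return parse_allele_report(str(path))


def filter_by_zygosity(
    records: Sequence[AlleleAnnotationRecord],
    allowed_tokens: Iterable[str] = DEFAULT_ZYGOSITY_TOKENS,
) -> list[AlleleAnnotationRecord]:
    """Keep records whose zygosity class is allowed (case-insensitive)."""
    allowed = {t.lower() for t in allowed_tokens}
    if not allowed:
        raise ValueError("allowed zygosity token set is empty")
    return [r for r in records if r.zygosity_category.lower() in allowed]


def propagate_and_truncate(
    records: Sequence[AlleleAnnotationRecord],
    ontology: Ontology,
    max_level: int = DEFAULT_MAX_LEVEL,
    excluded_term_names: Iterable[str] = DEFAULT_EXCLUDED_TERM_NAMES,
) -> GeneTermAnnotation:
    """Build per-gene propagated, truncated, exclusion-filtered term sets.

    Per gene: the union over its records of (direct terms plus all their
    is_a ancestors), restricted to levels 1..max_level, minus the
    descendant closures of the excluded terms, minus the root.  Exclusion
    is applied after propagation, so a legitimate abnormal term still
    contributes its ancestors even when a sibling path is excluded.
    """
    if max_level < 1:
        raise ValueError(f"max_level must be >= 1, got {max_level}")
    try:
        excluded_ids = [ontology.id_of_name(n) for n in excluded_term_names]
    except KeyError as e:
        raise ValueError(f"excluded term name not found in ontology: {e}") from e
    excluded = ontology.descendant_closure(excluded_ids) if excluded_ids else set()

    genes: dict[str, set[tuple[str, int]]] = {}
    dropped = 0
    for rec in records:
        bag = genes.setdefault(rec.mgi_id, set())
        for tid in rec.term_ids:
            if tid not in ontology:
                dropped += 1
                continue
            for t in {tid} | ontology.ancestors(tid):
                if t == ontology.root_id or t in excluded:
                    continue
                level = ontology.term_level(t)
                if 1 <= level <= max_level:
                    bag.add((t, level))
    # genes whose every term was excluded/truncated away keep an empty set
    genes = {g: s for g, s in genes.items() if s}
    if dropped:
        logger.info("dropped %d unresolvable direct term assignments", dropped)
    return GeneTermAnnotation(genes=genes, max_level=max_level, dropped_terms=dropped)


def annotation_status(
    uheg_ids: Iterable[str],
    records: Sequence[AlleleAnnotationRecord],
    annotation: GeneTermAnnotation,
) -> dict[str, str]:
    """Tri-state status per gene; records must already be zygosity-filtered."""
    with_record = {r.mgi_id for r in records}
    status = {}
    for g in uheg_ids:
        if annotation.terms_of(g):
            status[g] = "abnormal"
        elif g in with_record:
            status[g] = "mutant_no_abnormal"
        else:
            status[g] = "no_mutant"
    return status


def study_counts(records: Sequence[AlleleAnnotationRecord]) -> dict[str, int]:
    """Distinct nonempty study identifiers per gene."""
    studies: dict[str, set[str]] = {}
    for r in records:
        bag = studies.setdefault(r.mgi_id, set())
        if r.study_id:
            bag.add(r.study_id)
    return {g: len(s) for g, s in studies.items()}


def write_gene_annotations(
    annotation: GeneTermAnnotation,
    ontology: Ontology,
    path: str | Path,
    gene_symbols: Mapping[str, str] | None = None,
) -> None:
    """One row per (gene, term, level), sorted; machine-readable summary."""
    rows = []
    for g in sorted(annotation.genes):
        for tid, level in sorted(annotation.genes[g], key=lambda x: (x[1], x[0])):
            rows.append(
                (
                    g,
                    (gene_symbols or {}).get(g, ""),
                    tid,
                    ontology.name(tid),
                    level,
                )
            )
    pd.DataFrame(
        rows, columns=["mgi_id", "gene_symbol", "term_id", "term_name", "level"]
    ).to_csv(path, sep="\t", index=False)
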