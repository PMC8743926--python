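"""Counting surfaces over per-gene phenotype annotation sets.

Per-level term-by-gene-count tables with integer percentages of the UHEG
total, top-term rankings, multi-term membership queries, terms-per-gene and
studies-per-gene histograms, and overlap with a curated housekeeping-gene
list.  Percentages use round-half-away-from-zero of 100*k/n, the
convention consistent with every printed (count, %) pair in the reference
first-level term table at a 547-gene total.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneTermAnnotation
from .ontology import Ontology

__all__ = [
    "TermSummary",
    "HistogramRow",
    "percent",
    "term_gene_count_table",
    "genes_with_at_least",
    "annotation_histogram",
    "housekeeping_overlap",
    "read_housekeeping_list",
    "write_term_table",
    "DEFAULT_HISTOGRAM_BINS",
]

# terms-per-gene bins used in the reference summary: 1-5, 6-9, >=10
DEFAULT_HISTOGRAM_BINS = ((1, 5), (6, 9), (10, None))


@dataclass(frozen=True)
class TermSummary:
    term_id: str
    term_name: str
    level: int
    gene_count: int
    percent: int


@dataclass(frozen=True)
class HistogramRow:
    label: str
    lo: int
    hi: int | None  # None = unbounded
    gene_count: int


def percent(k: int, n: int) -> int:
    """Integer percentage, round half away from zero: round(100*k/n)."""
    if n <= 0:
        raise ValueError(f"total must be positive, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"count {k} outside [0, {n}]")
    # integer arithmetic avoids float half-point artifacts
    return (200 * k + n) // (2 * n)


def term_gene_count_table(
    annotation: GeneTermAnnotation,
    ontology: Ontology,
    level: int,
    total: int,
) -> list[TermSummary]:
    """Distinct-gene counts per term at one ontology level.

    One row per term with at least one gene, sorted by gene count
    descending then term name ascending.
    """
    if not 1 <= level <= annotation.max_level:
        raise ValueError(f"level {level} outside 1..{annotation.max_level}")
    counts: dict[str, int] = {}
    for terms in annotation.genes.values():
        for tid, lv in terms:
            if lv == level:
                counts[tid] = counts.get(tid, 0) + 1
    rows = [
        TermSummary(tid, ontology.name(tid), level, c, percent(c, total))
        for tid, c in counts.items()
    ]
    rows.sort(key=lambda r: (-r.gene_count, r.term_name))
    return rows


def genes_with_at_least(
    annotation: GeneTermAnnotation, term_set: Iterable[str], k: int
) -> set[str]:
    """Genes whose annotation intersects ``term_set`` in at least k terms."""
    if k < 0:
        raise ValueError("k must be >= 0")
    term_set = set(term_set)
    out = set()
    for g, terms in annotation.genes.items():
        if len({t for t, _ in terms} & term_set) >= k:
            out.add(g)
    if k == 0:
        out = set(annotation.genes)
    return out


@dataclass
class HistogramResult:
    terms_per_gene: list[HistogramRow]
    studies_per_gene: list[HistogramRow]
    max_terms: int
    argmax_genes: list[str]  # genes attaining max_terms, sorted


def _bin_rows(
    counts: Mapping[str, int], bins: Sequence[tuple[int, int | None]]
) -> list[HistogramRow]:
    inf = float("inf")
    spans = [(lo, inf if hi is None else hi) for lo, hi in bins]
    for i, (lo1, hi1) in enumerate(spans):
        for lo2, hi2 in spans[i + 1 :]:
            if lo1 <= hi2 and lo2 <= hi1:
                raise ValueError(f"overlapping bins ({lo1},{hi1}) and ({lo2},{hi2})")
    uncovered = [
        c for c in counts.values() if not any(lo <= c <= (hi if hi is not None else c) for lo, hi in bins)
    ]
    if uncovered:
        raise ValueError(f"bins do not cover observed count {uncovered[0]}")
    rows = []
    for lo, hi in bins:
        n = sum(1 for c in counts.values() if lo <= c and (hi is None or c <= hi))
        label = f"{lo}-{hi}" if hi is not None else f">={lo}"
        rows.append(HistogramRow(label, lo, hi, n))
    return rows


def annotation_histogram(
    annotation: GeneTermAnnotation,
    study_counts: Mapping[str, int] | None = None,
    bins: Sequence[tuple[int, int | None]] = DEFAULT_HISTOGRAM_BINS,
    level: int | None = None,
) -> HistogramResult:
    """Histogram genes by terms-per-gene (and optionally studies-per-gene).

    Only genes with a nonempty (abnormal) annotation set contribute.  With
    ``level`` set, only terms at that exact level are counted.  Also
    reports the maximum terms-per-gene and which genes attain it.
    """
    tpg = {}
    for g, terms in annotation.genes.items():
        n = sum(1 for _, lv in terms if level is None or lv == level)
        if n > 0:
            tpg[g] = n
    term_rows = _bin_rows(tpg, bins)
    study_rows = []
    if study_counts:
        positive = {g: c for g, c in study_counts.items() if g in tpg and c > 0}
        study_rows = _bin_rows(positive, bins)
    max_terms = max(tpg.values()) if tpg else 0
    argmax = sorted(g for g, c in tpg.items() if c == max_terms) if tpg else []
    return HistogramResult(term_rows, study_rows, max_terms, argmax)


def read_housekeeping_list(path: str | Path) -> list[str]:
    """Plain-text housekeeping gene list, one symbol per line."""
    out = []
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym:
            out.append(sym)
    return out


def housekeeping_overlap(
    uheg_symbols: Mapping[str, str],
    housekeeping_symbols: Iterable[str],
    status: Mapping[str, str],
) -> dict[str, int]:
    """Overlap of UHEGs with a housekeeping-gene list, by exact symbol match.

    ``uheg_symbols`` maps MGI ID -> gene symbol.  Returns counts of UHEGs
    in the list, the subset with an abnormal annotation, and both as
    integer percentages of the UHEG total.
    """
    hk = {s.strip() for s in housekeeping_symbols if s.strip()}
    if not hk:
        raise ValueError("housekeeping list is empty")
    total = len(uheg_symbols)
    in_hk = {g for g, sym in uheg_symbols.items() if sym.strip() in hk}
    in_hk_abnormal = {g for g in in_hk if status.get(g) == "abnormal"}
    return {
        "n_in_hk": len(in_hk),
        "n_in_hk_abnormal": len(in_hk_abnormal),
        "pct_in_hk": percent(len(in_hk), total) if total else 0,
        "pct_in_hk_abnormal": percent(len(in_hk_abnormal), total) if total else 0,
    }


def write_term_table(rows: Sequence[TermSummary], path: str | Path) -> None:
    pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "term_name": [r.term_name for r in rows],
            "level": [r.level for r in rows],
            "gene_count": [r.gene_count for r in rows],
            "percent": [r.percent for r in rows],
        }
    ).to_csv(path, sep="\t", index=False)
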