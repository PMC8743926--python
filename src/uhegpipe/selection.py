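"""Unique Highly Expressed Gene (UHEG) selection.

The selection cascade: per-sample top-K probes by normalized expression,
intersection over every sample required for the intersection (samples can
be exempted, as the postnatal-day-1 arrays are in the reference analysis),
removal of probes not annotated as protein coding, and collapse of
redundant probes to one record per gene identifier.  A per-gene expression
variance across retained samples quantifies expression stability.

Ties at rank K are broken deterministically: value descending, then probe
ID ascending, taking exactly K probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, ConsistencyError

__all__ = [
    "ProbeAnnotation",
    "ProbeGeneMap",
    "UhegRecord",
    "read_probe_map",
    "top_k_probes",
    "intersect_required",
    "filter_protein_coding",
    "collapse_to_unique_genes",
    "per_gene_variance",
    "write_uheg_table",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 1500
PROTEIN_CODING = "protein coding gene"


@dataclass(frozen=True)
class ProbeAnnotation:
    gene_symbol: str
    mgi_id: str
    feature_type: str


ProbeGeneMap = Mapping[str, ProbeAnnotation]


@dataclass(frozen=True)
class UhegRecord:
    mgi_id: str
    gene_symbol: str
    representative_probe: str
    mean_expression: float
    expression_variance: float


def read_probe_map(path: str | Path) -> dict[str, ProbeAnnotation]:
    """Read probe annotation TSV (probe_id, gene_symbol, mgi_id, feature_type).

    Column subset compatible with an MGI Batch Query export.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"probe_id", "gene_symbol", "mgi_id", "feature_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe map missing columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe ID in map: {dup!r}")
    return {
        r.probe_id: ProbeAnnotation(r.gene_symbol, r.mgi_id, r.feature_type)
        for r in df.itertuples(index=False)
    }


def top_k_probes(matrix: ExpressionMatrix, sample_id: str, k: int = DEFAULT_K) -> set[str]:
    """The min(k, P) most highly expressed probes in one sample.

    Total order: value descending, then probe ID ascending.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if sample_id not in matrix.values.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    col = matrix.values[sample_id]
    order = sorted(zip(-col.to_numpy(), col.index))
    return {probe for _, probe in order[:k]}


def intersect_required(
    per_sample_topk: Mapping[str, set[str]],
    required_sample_ids: Iterable[str],
) -> set[str]:
    """Intersect top-K sets over the required samples only."""
    required = list(required_sample_ids)
    if not required:
        raise ValueError("required sample set is empty")
    missing = [s for s in required if s not in per_sample_topk]
    if missing:
        raise KeyError(f"no top-K set for required samples: {missing}")
    out = set(per_sample_topk[required[0]])
    for s in required[1:]:
        out &= per_sample_topk[s]
    return out


def filter_protein_coding(
    probes: Iterable[str],
    probe_map: ProbeGeneMap,
    required_feature_type: str = PROTEIN_CODING,
) -> set[str]:
    """Retain probes annotated with the required MGI Feature Type.

    Probes absent from the map cannot demonstrate the required feature
    type and are dropped, with a logged count.
    """
    probes = set(probes)
    unmapped = {p for p in probes if p not in probe_map}
    if unmapped:
        logger.info("dropping %d probes absent from the annotation map", len(unmapped))
    return {
        p
        for p in probes - unmapped
        if probe_map[p].feature_type == required_feature_type
    }


def collapse_to_unique_genes(
    probes: Iterable[str],
    probe_map: ProbeGeneMap,
    matrix: ExpressionMatrix,
) -> list[UhegRecord]:
    """Collapse redundant probes to one record per MGI gene ID.

    The representative probe is the one with the highest mean expression
    over retained samples (probe-ID ascending on ties).  Returns records
    sorted by gene symbol then MGI ID.
    """
    by_gene: dict[str, list[str]] = {}
    symbols: dict[str, str] = {}
    for p in sorted(probes):
        ann = probe_map[p]
        if not ann.mgi_id:
            raise ValueError(f"probe {p!r} has no MGI ID")
        if ann.mgi_id in symbols and symbols[ann.mgi_id] != ann.gene_symbol:
            raise ConsistencyError(
                f"MGI ID {ann.mgi_id} maps to conflicting symbols "
                f"{symbols[ann.mgi_id]!r} and {ann.gene_symbol!r}"
            )
        symbols[ann.mgi_id] = ann.gene_symbol
        by_gene.setdefault(ann.mgi_id, []).append(p)

    records = []
    for mgi_id, gene_probes in by_gene.items():
        means = {p: float(matrix.values.loc[p].mean()) for p in gene_probes}
        rep = min(means, key=lambda p: (-means[p], p))
        values = matrix.values.loc[rep].to_numpy()
        var = float(np.var(values, ddof=1)) if len(values) > 1 else 0.0
        records.append(
            UhegRecord(
                mgi_id=mgi_id,
                gene_symbol=symbols[mgi_id],
                representative_probe=rep,
                mean_expression=means[rep],
                expression_variance=var,
            )
        )
    records.sort(key=lambda r: (r.gene_symbol, r.mgi_id))
    return records


def per_gene_variance(
    records: Sequence[UhegRecord],
    matrix: ExpressionMatrix,
    threshold: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Unbiased (n-1) variance of each representative probe across samples.

    Returns the per-gene table and the fraction of genes with variance
    strictly below ``threshold``.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("variance requires at least 2 samples")
    rows = []
    for r in records:
        if r.representative_probe not in matrix.values.index:
            raise KeyError(f"probe {r.representative_probe!r} not in matrix")
        v = float(np.var(matrix.values.loc[r.representative_probe].to_numpy(), ddof=1))
        rows.append((r.mgi_id, r.gene_symbol, r.representative_probe, v))
    table = pd.DataFrame(
        rows, columns=["mgi_id", "gene_symbol", "representative_probe", "variance"]
    )
    frac = float((table["variance"] < threshold).mean()) if len(table) else 0.0
    return table, frac


def write_uheg_table(records: Sequence[UhegRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "mgi_id": [r.mgi_id for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "representative_probe": [r.representative_probe for r in records],
            "mean_expression": [f"{r.mean_expression:.4f}" for r in records],
            "expression_variance": [f"{r.expression_variance:.6f}" for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
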