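"""Expression-matrix I/O and per-array quality-control filtering.

The pipeline consumes normalized log2 expression matrices (one per
experiment, probes x samples) together with a sample sheet describing each
array (experiment, postnatal day, replicate) and a per-array QC metrics
table.  Arrays are excluded when their background score exceeds the
background threshold or when the 3'/5' degradation ratios for beta-actin or
GAPDH exceed their absolute-value thresholds.  All comparisons are strict,
so an array sitting exactly on a threshold is kept.

Computation of the QC metrics themselves (from raw CEL files) and RMA
normalization are upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "ExpressionMatrix",
    "QCMetrics",
    "QCThresholds",
    "QCResult",
    "read_sample_sheet",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_sample_sheet",
    "concat_experiments",
    "read_qc_metrics",
    "apply_qc_filters",
]


class FormatError(ValueError):
    """Malformed input file (duplicate IDs, missing columns, ...)."""


class ConsistencyError(ValueError):
    """Cross-file inconsistency (e.g. matrix sample absent from the sheet)."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one array/sample.

    ``required_for_intersection`` implements the exemption of selected
    samples (postnatal-day-1 arrays in the reference analysis) from the
    all-sample top-K intersection requirement.
    """

    sample_id: str
    experiment_id: str
    postnatal_day: int
    replicate: int
    required_for_intersection: bool = True

    def __post_init__(self) -> None:
        if self.postnatal_day < 0:
            raise ValueError(
                f"postnatal_day must be >= 0, got {self.postnatal_day} "
                f"for sample {self.sample_id!r}"
            )


@dataclass
class ExpressionMatrix:
    """Normalized log2 intensities, probes x samples, with sample metadata.

    ``values`` is a DataFrame indexed by probe ID with one column per
    sample, column order following ``samples``.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample IDs in metadata")
        if list(self.values.columns) != ids:
            raise ConsistencyError(
                "matrix columns do not match sample metadata order"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()]
            raise FormatError(f"duplicate probe IDs: {sorted(set(dups))[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise FormatError("expression matrix contains non-finite values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = set(keep)
        samples = [s for s in self.samples if s.sample_id in keep]
        cols = [s.sample_id for s in samples]
        return ExpressionMatrix(self.values[cols], samples)


@dataclass(frozen=True)
class QCMetrics:
    """Per-array QC scores: background plus signed 3'/5' degradation ratios."""

    sample_id: str
    background: float
    actin_ratio: float
    gapdh_ratio: float

    def __post_init__(self) -> None:
        for name in ("background", "actin_ratio", "gapdh_ratio"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(
                    f"missing QC metric {name!r} for sample {self.sample_id!r}"
                )


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; an array is dropped on a strict exceedance."""

    background_max: float = 90.0
    actin_abs_max: float = 3.0
    gapdh_abs_max: float = 1.0

    def __post_init__(self) -> None:
        for name in ("background_max", "actin_abs_max", "gapdh_abs_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class QCResult:
    kept: list[str]
    excluded: dict[str, list[str]]  # sample_id -> violated reason codes


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the sample sheet TSV.

    Columns: sample_id, experiment_id, postnatal_day, replicate,
    required_for_intersection (true/false).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "sample_id",
        "experiment_id",
        "postnatal_day",
        "replicate",
        "required_for_intersection",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        flag = str(row.required_for_intersection).strip().lower()
        if flag not in {"true", "false"}:
            raise FormatError(
                f"required_for_intersection must be true/false, got {flag!r}"
            )
        out.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                experiment_id=str(row.experiment_id),
                postnatal_day=int(row.postnatal_day),
                replicate=int(row.replicate),
                required_for_intersection=flag == "true",
            )
        )
    ids = [s.sample_id for s in out]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample IDs in sample sheet")
    return out


def read_expression_matrix(
    matrix_path: str | Path, sample_sheet_path: str | Path
) -> ExpressionMatrix:
    """Read one experiment's expression TSV plus the run's sample sheet.

    The first column holds probe IDs; remaining columns are sample IDs.
    The sheet may describe more samples than this matrix (other
    experiments); every matrix column must appear in the sheet.
    """
    sheet = read_sample_sheet(sample_sheet_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()]
        raise FormatError(f"duplicate probe IDs: {sorted(set(dups))[:5]}")
    by_id = {s.sample_id: s for s in sheet}
    missing = [c for c in df.columns if c not in by_id]
    if missing:
        raise ConsistencyError(
            f"matrix samples missing from sample sheet: {missing}"
        )
    # column order follows the sheet, restricted to this matrix's samples
    cols = [s.sample_id for s in sheet if s.sample_id in set(df.columns)]
    samples = [by_id[c] for c in cols]
    return ExpressionMatrix(df[cols].astype(float), samples)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.4f"
) -> None:
    matrix.values.to_csv(
        path, sep="\t", index_label="probe_id", float_format=float_format
    )


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "experiment_id": [s.experiment_id for s in samples],
            "postnatal_day": [s.postnatal_day for s in samples],
            "replicate": [s.replicate for s in samples],
            "required_for_intersection": [
                str(s.required_for_intersection).lower() for s in samples
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def concat_experiments(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate per-experiment matrices sharing one probe universe.

    Experiments are normalized separately upstream; their matrices are only
    joined here, after reading.  Probe sets must agree exactly.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    base = matrices[0]
    for m in matrices[1:]:
        if list(m.values.index) != list(base.values.index):
            raise ConsistencyError("experiments have differing probe sets")
    values = pd.concat([m.values for m in matrices], axis=1)
    samples = [s for m in matrices for s in m.samples]
    return ExpressionMatrix(values, samples)


def read_qc_metrics(path: str | Path) -> list[QCMetrics]:
    """Read the QC metrics TSV (sample_id, background, actin_ratio, gapdh_ratio)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "background", "actin_ratio", "gapdh_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"QC metrics missing columns: {sorted(missing)}")
    return [
        QCMetrics(
            sample_id=str(r.sample_id),
            background=float(r.background),
            actin_ratio=float(r.actin_ratio),
            gapdh_ratio=float(r.gapdh_ratio),
        )
        for r in df.itertuples(index=False)
    ]


def apply_qc_filters(
    metrics: Sequence[QCMetrics], thresholds: QCThresholds | None = None
) -> QCResult:
    """Partition arrays into kept and excluded per the exclusion thresholds.

    An array is excluded iff background > background_max OR
    |actin_ratio| > actin_abs_max OR |gapdh_ratio| > gapdh_abs_max; the
    exclusion record carries every violated reason code.  Strict
    inequalities: boundary arrays are kept.
    """
    if not metrics:
        raise ValueError("QC metrics table is empty")
    thresholds = thresholds or QCThresholds()
    kept: list[str] = []
    excluded: dict[str, list[str]] = {}
    for m in metrics:
        reasons = []
        if m.background > thresholds.background_max:
            reasons.append("background")
        if abs(m.actin_ratio) > thresholds.actin_abs_max:
            reasons.append("actin")
        if abs(m.gapdh_ratio) > thresholds.gapdh_abs_max:
            reasons.append("gapdh")
        if reasons:
            excluded[m.sample_id] = reasons
        else:
            kept.append(m.sample_id)
    return QCResult(kept=kept, excluded=excluded)
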