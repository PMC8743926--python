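"""Run configuration: one YAML file holding every pipeline constant.

Each analysis constant is a named, defaulted key, so the reference run
(top-K = 1500, four annotation levels, the standard QC thresholds,
heterozygous/homozygous zygosity classes, variance threshold 1) is the
default run.  Unknown keys are rejected outright — a typo must never
silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import yaml

from .expression import QCThresholds

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


_INPUT_KEYS = (
    "sample_sheet",
    "qc_metrics",
    "probe_map",
    "ontology",
    "allele_report",
    "housekeeping",
)


@dataclass
class RunConfig:
    expression_matrices: list[Path]
    sample_sheet: Path
    qc_metrics: Path
    probe_map: Path
    ontology: Path
    allele_report: Path
    housekeeping: Path
    k: int = 1500
    max_level: int = 4
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    zygosity_tokens: tuple[str, ...] = ("hm", "ht")
    excluded_term_names: tuple[str, ...] = ("normal phenotype", "no phenotypic analysis")
    feature_type: str = "protein coding gene"
    variance_threshold: float = 1.0
    pair_levels: tuple[int, ...] = (4,)
    output_dir: Path = Path("results")
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if self.max_level < 1:
            raise ConfigError(f"max_level must be >= 1, got {self.max_level}")
        if any(lv < 1 or lv > self.max_level for lv in self.pair_levels):
            raise ConfigError(f"pair_levels outside 1..{self.max_level}")
        if self.variance_threshold <= 0:
            raise ConfigError("variance_threshold must be positive")
        if not self.zygosity_tokens:
            raise ConfigError("zygosity_tokens is empty")
        for p in self.expression_matrices:
            if not Path(p).exists():
                raise ConfigError(f"expression matrix not found: {p}")
        for key in _INPUT_KEYS:
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigError(f"{key} file not found: {p}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["expression_matrices"] = [str(p) for p in self.expression_matrices]
        for key in _INPUT_KEYS + ("output_dir",):
            d[key] = str(d[key])
        d["qc_thresholds"] = asdict(self.qc_thresholds)
        d["zygosity_tokens"] = list(self.zygosity_tokens)
        d["excluded_term_names"] = list(self.excluded_term_names)
        d["pair_levels"] = list(self.pair_levels)
        return d


_KNOWN_KEYS = {
    "expression_matrices",
    *_INPUT_KEYS,
    "k",
    "max_level",
    "qc_thresholds",
    "zygosity_tokens",
    "excluded_term_names",
    "feature_type",
    "variance_threshold",
    "pair_levels",
    "output_dir",
    "seed",
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Relative input paths resolve against the config file's directory.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    missing = ({"expression_matrices", *_INPUT_KEYS}) - set(raw)
    if missing:
        raise ConfigError(f"missing required config keys: {sorted(missing)}")

    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    kwargs: dict[str, Any] = {
        "expression_matrices": [resolve(p) for p in raw["expression_matrices"]],
    }
    for key in _INPUT_KEYS:
        kwargs[key] = resolve(raw[key])
    if "qc_thresholds" in raw:
        kwargs["qc_thresholds"] = QCThresholds(**raw["qc_thresholds"])
    for key in ("k", "max_level", "feature_type", "variance_threshold", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("zygosity_tokens", "excluded_term_names", "pair_levels"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    if "output_dir" in raw:
        kwargs["output_dir"] = resolve(raw["output_dir"])

    config = RunConfig(**kwargs)
    config.validate()
    return config
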