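"""Declarative pipeline configuration (YAML file + programmatic overrides)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import yaml

from .expression import DEFAULT_STRINGENCIES


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, with validated defaults.

    Paths are the five pipeline inputs; the remaining fields are the
    screening, locus and CNV parameters with their documented defaults.
    """

    # inputs
    expression: str = "expression.tsv"
    groups: str = "groups.tsv"
    gene_models: str = "gene_models.bed"
    markers: str = "markers.tsv"
    cnv_calls: str = "cnv_calls.tsv"
    probe_gene_map: str = "probe_gene_map.tsv"
    # expression screen
    stringencies: Sequence[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_STRINGENCIES)
    )
    fdr_boot_agg: Literal["first_two", "mean_all"] = "first_two"
    min_exp: int = 10
    robust_thresh: float = 0.585
    robust_min_count: int = 9
    # gwas locus
    pad: int = 20000
    alpha: float = 0.05
    # cnv refinement
    cnv_min_markers: int = 10
    outlier_rule: str | list[str] = "mad"
    # run
    seed: int = 0
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if not self.stringencies:
            raise ConfigError("stringencies must be non-empty")
        self.stringencies = [
            (float(a), float(p)) for a, p in self.stringencies
        ]
        for a, p in self.stringencies:
            if a < 0 or not (0 < p <= 1):
                raise ConfigError(f"invalid stringency ({a}, {p})")
        if self.fdr_boot_agg not in ("first_two", "mean_all"):
            raise ConfigError(f"unknown fdr_boot_agg: {self.fdr_boot_agg}")
        if self.min_exp < 1 or self.robust_min_count < 0:
            raise ConfigError("count thresholds must be positive")
        if self.robust_thresh < 0 or self.pad < 0 or self.cnv_min_markers < 1:
            raise ConfigError("thresholds out of range")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; unknown keys are rejected, not ignored."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stringencies"] = [list(s) for s in self.stringencies]
        return d

    def digest(self) -> str:
        """Stable hash of the analysis parameters, for provenance.

        The output directory is excluded: it locates results but does not
        influence them.
        """
        d = self.to_dict()
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
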