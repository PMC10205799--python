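"""Pipeline configuration: YAML-backed, defaulted, range-checked.

Defaults mirror the analysis conventions the pipeline implements: QC at
200 / 10,000 detected genes (strict removal), normalization scale 1e4,
module scoring with 24 bins x 100 controls, ancestor voting with k=5, and
subcluster selection at >10% CM fraction with >=10 supporting cells.
Unknown keys are an error so typos never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

STAGES_DEFAULT = ["0w", "2w", "5w", "8w", "11w"]


@dataclass
class PipelineConfig:
    stages: list[str] = field(default_factory=lambda: list(STAGES_DEFAULT))
    min_genes: int = 200
    max_genes: int = 10000
    scale_factor: float = 1e4
    n_hvg: int = 2000
    gene_set_path: str | None = None       # None -> packaged MAM set
    n_bins: int = 24
    n_ctrl: int = 100
    k: int = 5
    min_frac: float = 0.10
    min_support: int = 10
    gene_universe: str = "hvg"             # "hvg" | "all"
    ancestry_n_hvg: int = 500
    strict_consistency: bool = False
    trend_window: int = 51
    trend_epsilon: float = 0.05
    trend_genes: list[str] = field(default_factory=lambda: ["Mfn1", "Hspa9"])
    score_subtypes: list[str] = field(default_factory=lambda: ["CM2", "CM3"])
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if len(set(self.stages)) != len(self.stages) or not self.stages:
            raise ValueError("stages must be a non-empty list of unique labels")
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if self.max_genes < self.min_genes:
            raise ValueError("max_genes must be >= min_genes")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        for name in ("n_hvg", "n_bins", "n_ctrl", "k", "min_support",
                     "ancestry_n_hvg", "trend_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.min_frac <= 1.0):
            raise ValueError("min_frac must be in [0, 1]")
        if not (0.0 <= self.trend_epsilon <= 1.0):
            raise ValueError("trend_epsilon must be in [0, 1]")
        if self.gene_universe not in ("hvg", "all"):
            raise ValueError("gene_universe must be 'hvg' or 'all'")
        if self.seed < 0 or self.seed >= 2 ** 31:
            raise ValueError("seed must be in [0, 2^31)")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(path_or_dict) -> PipelineConfig:
    """Load a YAML config (an empty file means all defaults); unknown keys
    and out-of-range values raise with the offending fields named."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict or {})
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return PipelineConfig(**raw).validate()
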