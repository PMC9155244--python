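"""Pipeline configuration: the thresholds used at every stage.

Defaults mirror the analysis contract: differential expression at FDR < 0.1,
differential splicing at FDR < 0.1 and |dPSI| >= 0.05, co-expression edges at
|r| > 0.9 with hub highlighting above degree 15 and a top-20% hub cut, six
profile clusters under complete linkage with Minkowski distance, and
250 bp binding-region flanks with 10 bp splice-site-adjacent trims.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class Config:
    fdr_deg: float = 0.1
    fdr_splice: float = 0.1
    dpsi_min: float = 0.05
    r_threshold: float = 0.9
    hub_degree_min: int = 15
    hub_top_frac: float = 0.2
    n_clusters: int = 6
    minkowski_order: float = 2.0
    flank_bp: int = 250
    trim_bp: int = 10
    alpha_enrich: float = 0.05
    gamma_gap: float = 0.67  # gap-closure fraction separating sensitive from graded response
    seed: int = 0

    def __post_init__(self):
        for name in ("fdr_deg", "fdr_splice", "dpsi_min", "r_threshold",
                     "hub_top_frac", "alpha_enrich"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.minkowski_order < 1:
            raise ValueError("minkowski_order must be >= 1")
        if self.flank_bp < 0 or self.trim_bp < 0:
            raise ValueError("flank_bp and trim_bp must be >= 0")
        if self.hub_degree_min < 0:
            raise ValueError("hub_degree_min must be >= 0")


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Load a Config from YAML, applying keyword overrides on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return Config(**data)
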