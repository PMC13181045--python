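"""Run configuration: a typed YAML schema for reproducible pipeline runs.

Unknown keys anywhere in the document are rejected (typo guard) with a
message naming the offending key; every tunable constant of the analysis
(sampling lattice, caps, depth strata, matchup thresholds, LQ filter) is
surfaced here so tests can perturb it.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from pathlib import Path

import yaml
from pydantic import Field, field_validator

from .params import (
    ArgoSimParams,
    Bbox,
    ModelProductParams,
    OceanTruthParams,
    TurtleSimParams,
    _Params,
)


class AnalysisParams(_Params):
    """Decoding and matchup/statistics settings."""

    allowed_lq: list[str] = Field(default_factory=lambda: ["0"])
    truncate: str = "suffix"
    max_match_km: float = Field(25.0, gt=0)
    single_sample_tol_m: float = Field(2.5, ge=0)
    strata: list[str] = Field(default_factory=lambda: ["season", "depth_range"])
    argo_max_dist_km: float = Field(10.0, gt=0)
    argo_max_days: float = Field(15.0, gt=0)
    argo_dz_m: float = Field(1.0, gt=0)
    argo_zmax_m: float = Field(12.0, gt=0)

    @field_validator("truncate")
    @classmethod
    def _trunc(cls, v):
        if v not in ("suffix", "prefix"):
            raise ValueError("truncate must be 'suffix' or 'prefix'")
        return v


class RunConfig(_Params):
    """Top-level configuration for an end-to-end synthetic run."""

    seed: int = Field(0, ge=0, lt=2**31)
    start_date: dt.date = dt.date(2021, 1, 1)
    end_date: dt.date = dt.date(2021, 12, 31)
    bbox: Bbox = Field(default_factory=Bbox)
    ocean: OceanTruthParams = Field(default_factory=OceanTruthParams)
    product: ModelProductParams = Field(default_factory=ModelProductParams)
    turtles: TurtleSimParams = Field(default_factory=TurtleSimParams)
    argo: ArgoSimParams = Field(default_factory=ArgoSimParams)
    analysis: AnalysisParams = Field(default_factory=AnalysisParams)
    regions_file: str | None = None  # None → packaged default polygons

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]

    def resolve_seeds(self) -> "RunConfig":
        """Derive per-generator seeds from the run seed (stable, independent)."""
        import numpy as np

        children = np.random.SeedSequence(self.seed).generate_state(3) % (2**31)
        cfg = self.model_copy(deep=True)
        cfg.product.seed = int(children[0])
        cfg.turtles.seed = int(children[1])
        cfg.argo.seed = int(children[2])
        return cfg


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
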