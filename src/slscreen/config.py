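"""Validated pipeline configuration.

A single schema covers every stage; unknown keys are rejected so typos never
silently fall back to defaults, and the fully resolved config (defaults
filled in) is written next to the outputs of each run.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .simulate import CONTROL_SAMPLES, KO_SAMPLES, SimulationParams

__all__ = ["PipelineConfig", "load_config", "PathsConfig", "DesignConfig",
           "HitcallConfig", "CountConfig", "EnrichConfig"]


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    library: Optional[str] = None
    counts: Optional[str] = None
    fastq: dict[str, str] = Field(default_factory=dict)  # sample id -> path
    gmt: Optional[str] = None


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    ko_samples: tuple[str, str] = KO_SAMPLES
    control_samples: tuple[str, str] = CONTROL_SAMPLES


class CountConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_mismatch: int = Field(0, ge=0)
    offset: int = Field(0, ge=0)
    try_revcomp: bool = False


class HitcallConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pseudocount: float = Field(1.0, ge=0)
    normalization: Literal["raw", "cpm"] = "cpm"
    fold_threshold: float = Field(5.0, gt=1)
    min_depleted: int = Field(2, ge=1)
    min_fivefold: int = Field(1, ge=0)
    min_count: int = Field(10, ge=0)
    include_controls: bool = True
    threshold_z: float = -1.5


class EnrichConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(0.01, gt=0, le=1)
    edge_threshold: float = Field(0.25, ge=0, le=1)


class PipelineConfig(BaseModel):
    """Top-level config: paths, screen design, stage parameters, seed."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    paths: PathsConfig = Field(default_factory=PathsConfig)
    design: DesignConfig = Field(default_factory=DesignConfig)
    count: CountConfig = Field(default_factory=CountConfig)
    hitcall: HitcallConfig = Field(default_factory=HitcallConfig)
    enrich: EnrichConfig = Field(default_factory=EnrichConfig)
    simulate: Optional[SimulationParams] = None
    emit_fastq: bool = False

    @model_validator(mode="after")
    def _check_inputs(self) -> "PipelineConfig":
        has_input = (
            self.simulate is not None
            or self.paths.counts is not None
            or bool(self.paths.fastq)
        )
        if not has_input:
            raise ValueError(
                "config must provide a simulate block, a counts path, or "
                "fastq paths"
            )
        return self

    def resolved(self) -> dict:
        return self.model_dump(mode="json")

    def write_resolved(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=True)


def load_config(path: str | Path, seed: Optional[int] = None) -> PipelineConfig:
    """Load and validate a YAML config; an explicit seed overrides the file's."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.model_validate(data)
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
        if cfg.simulate is not None:
            cfg.simulate.seed = seed
    return cfg
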