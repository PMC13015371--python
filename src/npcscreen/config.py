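"""Pipeline configuration: a single validated YAML file.

The configuration has four sections — growth (simulation + fit options),
deg (simulation + per-contrast thresholds), io (paths) and the run-level
seed/log level.  Unknown keys are rejected.  The run seed propagates to
both simulation stages deterministically (growth stage uses the run seed,
DEG stage the run seed + 1), so one integer pins the whole run.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .concordance import ThresholdSpec
from .errors import ConfigurationError
from .simulate import DegSimConfig, GrowthSimConfig


class FitOptions(BaseModel):
    """Growth-fit options: QC span, replicate floor and fit-window start."""

    model_config = ConfigDict(extra="forbid")

    min_span_h: float = Field(default=48.0, gt=0)
    min_replicates: int = Field(default=3, ge=1)
    fit_start_h: float = Field(default=0.0, ge=0)


class GrowthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sim: GrowthSimConfig = Field(default_factory=GrowthSimConfig)
    fit: FitOptions = Field(default_factory=FitOptions)


class DegSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sim: DegSimConfig = Field(default_factory=DegSimConfig)
    genotype_thresholds: ThresholdSpec = Field(default_factory=ThresholdSpec)
    treatment_thresholds: ThresholdSpec = Field(default_factory=ThresholdSpec)


class IoSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    out_dir: str = "results"
    #: optional pre-existing inputs; when absent the stage simulates its input
    traces_csv: str | None = None
    genotype_table: str | None = None
    treatment_table: str | None = None


class PipelineConfig(BaseModel):
    """Validated end-to-end pipeline configuration."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    log_level: str = "INFO"
    growth: GrowthSection = Field(default_factory=GrowthSection)
    deg: DegSection = Field(default_factory=DegSection)
    io: IoSection = Field(default_factory=IoSection)

    @model_validator(mode="after")
    def _propagate_seed(self) -> "PipelineConfig":
        self.growth.sim.seed = self.seed
        self.deg.sim.seed = self.seed + 1
        return self

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration; defaults applied."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    payload = yaml.safe_load(path.read_text()) or {}
    try:
        return PipelineConfig.model_validate(payload)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration ({path.name}): {problems}") from exc


def published_defaults() -> PipelineConfig:
    """Named preset with the published screen's thresholds and design values."""
    cfg = PipelineConfig()
    cfg.deg.genotype_thresholds = ThresholdSpec(p_adj_max=0.05, abs_fc_min=1.5)
    cfg.deg.treatment_thresholds = ThresholdSpec(p_adj_max=0.05, abs_fc_min=1.5)
    return cfg
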