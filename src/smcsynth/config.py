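"""Run configuration: schema, loading, validation, resolution.

A run is fully described by a YAML file validated against the pydantic
schema below; every command writes the fully resolved configuration
(defaults included) next to its outputs so a run can be reproduced
bit-for-bit from the output directory alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .checking import BetaPrior, IndifferenceRegion, SPRTConfig
from .synthesis import AnnealingSchedule, NeighborhoodPolicy

__all__ = ["RunConfig", "CheckerConfig", "AnnealingConfig", "NeighborhoodConfig",
           "SpecConfig", "ConfigError", "load_config", "resolve_and_write"]


class ConfigError(ValueError):
    pass


class PriorConfig(BaseModel):
    a: float = 1.0
    b: float = 1.0


class CheckerConfig(BaseModel):
    theta: float = Field(ge=0.0, le=1.0)
    epsilon1: float = Field(default=0.05, gt=0.0)
    epsilon2: float = Field(default=0.05, gt=0.0)
    bayes_threshold: float = Field(default=100.0, gt=1.0)
    prior: PriorConfig = PriorConfig()
    max_samples: int = Field(default=100_000, ge=1)
    method: Literal["bayes", "sprt"] = "bayes"
    alpha: float = Field(default=0.01, gt=0.0, lt=1.0)
    beta: float = Field(default=0.01, gt=0.0, lt=1.0)

    def indifference(self) -> IndifferenceRegion:
        return IndifferenceRegion(self.epsilon1, self.epsilon2)

    def beta_prior(self) -> BetaPrior:
        return BetaPrior(self.prior.a, self.prior.b)

    def sprt_errors(self) -> SPRTConfig:
        return SPRTConfig(self.alpha, self.beta)


class AnnealingConfig(BaseModel):
    t_start: float = Field(default=100.0, gt=0.0)
    t_stop: float = Field(default=1.0, gt=0.0)
    gamma: float = Field(default=0.95, gt=0.0, lt=1.0)
    max_iterations: int = Field(default=10_000, ge=1)

    def schedule(self) -> AnnealingSchedule:
        return AnnealingSchedule(self.t_start, self.t_stop, self.gamma)


class NeighborhoodConfig(BaseModel):
    scale: float = Field(default=0.1, ge=0.0)
    mode: Literal["all", "one"] = "all"

    def policy(self) -> NeighborhoodPolicy:
        return NeighborhoodPolicy(self.scale, self.mode)


class SpecConfig(BaseModel):
    formula: Optional[str] = None      # inline BLTL text
    formula_file: Optional[str] = None  # one formula per line, first used

    @model_validator(mode="after")
    def _one_source(self):
        if (self.formula is None) == (self.formula_file is None):
            raise ValueError("give exactly one of spec.formula / spec.formula_file")
        return self


class ProfileConfig(BaseModel):
    grid: list[list[float]] = []
    runs: int = Field(default=200, ge=1)


class DemoConfig(BaseModel):
    spec_numbers: list[int] = [1, 2, 3, 4]
    joint: bool = False
    max_samples: int = Field(default=500, ge=1)
    max_iterations: int = Field(default=200, ge=1)
    plots: bool = False


class RunConfig(BaseModel):
    """Top-level run description (YAML)."""

    model: str                      # fixture name, or "air" for the demo
    omega: Optional[list[float]] = None
    spec: Optional[SpecConfig] = None
    checker: CheckerConfig
    annealing: AnnealingConfig = AnnealingConfig()
    neighborhood: NeighborhoodConfig = NeighborhoodConfig()
    profile: ProfileConfig = ProfileConfig()
    demo: DemoConfig = DemoConfig()
    seed: int = 0
    output_dir: str = "runs/out"


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; validation errors name
    the offending key paths."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"  {loc}: {err['msg']}")
        raise ConfigError("invalid configuration:\n" + "\n".join(lines)) from None


def resolve_and_write(config: RunConfig, out_dir: Path) -> None:
    """Persist the fully resolved config + version for reproducibility."""
    from . import __version__

    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = config.model_dump()
    resolved["_version"] = __version__
    with open(out_dir / "resolved_config.json", "w", encoding="utf-8") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True)
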