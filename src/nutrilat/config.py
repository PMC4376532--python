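"""Experiment configuration: schema, validation, defaults.

Configs are YAML (JSON is a YAML subset).  Environment presets name the
food-ratio sets used throughout: the V pool is {0.0625, 0.5, 1, 2, 16},
combined into 2- and 3-food environments of varying imbalance.  The presets
are declared interpretations (figure captions do not tabulate V per panel)
and can always be overridden with an explicit ratio list.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

__all__ = ["ENVIRONMENT_PRESETS", "ConfigError", "SelectionSettings",
           "CompositionGroup", "ExperimentConfig", "load_and_validate_config"]

ENVIRONMENT_PRESETS: dict[str, tuple[float, ...]] = {
    "3-food-mild": (0.5, 1.0, 2.0),
    "3-food-extreme": (0.0625, 1.0, 16.0),
    "2-food-mild": (1.0, 2.0),
    "2-food-severe": (1.0, 16.0),
    "2-food-complementary-mild": (0.5, 2.0),
    "2-food-complementary-extreme": (0.0625, 16.0),
}


class ConfigError(ValueError):
    """Itemised configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


class SelectionSettings(BaseModel):
    mode: Literal["general", "truncated"] = "general"
    fitness_cutoff: float = Field(0.5, gt=0.0, lt=1.0)
    truncation_fraction: float = Field(0.1, gt=0.0, le=1.0)
    mutation_sd: float = Field(0.025, ge=0.0)


class CompositionGroup(BaseModel):
    """A fixed-K subpopulation for single-generation experiments."""

    k: float = Field(ge=0.0, le=1.0)
    count: int = Field(gt=0)


class ExperimentConfig(BaseModel):
    environment: str | list[float]
    intake_target: tuple[float, float] = (500.0, 500.0)
    competition: list[float] = Field(min_length=1)
    eta: float = Field(25.0, gt=0.0)
    mu: float = Field(2.0, gt=0.0)
    phi: float = Field(2.0, gt=0.0)
    n_ind: int = Field(150, ge=1)
    n_iterations: int = Field(500, ge=1)
    n_generations: int = Field(1000, ge=1)
    selection: SelectionSettings = SelectionSettings()
    n_replicates: int = Field(30, ge=1)
    seed: int = 1
    composition: list[CompositionGroup] | None = None
    out_dir: str = "results"

    @field_validator("environment")
    @classmethod
    def _check_environment(cls, v):
        if isinstance(v, str):
            if v not in ENVIRONMENT_PRESETS:
                raise ValueError(
                    f"unknown environment preset {v!r}; known presets: "
                    + ", ".join(sorted(ENVIRONMENT_PRESETS)))
        else:
            if len(v) < 1:
                raise ValueError("environment ratio list must be non-empty")
            if any(x <= 0 for x in v):
                raise ValueError("food ratios V must be > 0")
        return v

    @field_validator("competition")
    @classmethod
    def _check_competition(cls, v):
        for c in v:
            if not (0.0 <= c < 1.0):
                raise ValueError(f"competition c must be in [0, 1); got {c}")
        return v

    @field_validator("intake_target")
    @classmethod
    def _check_it(cls, v):
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("intake target must be strictly positive in both nutrients")
        return v

    @model_validator(mode="after")
    def _check_composition(self):
        if self.composition is not None:
            total = sum(g.count for g in self.composition)
            if total != self.n_ind:
                raise ValueError(
                    f"composition counts sum to {total}, but n_ind = {self.n_ind}")
        return self

    @property
    def food_ratios(self) -> tuple[float, ...]:
        if isinstance(self.environment, str):
            return ENVIRONMENT_PRESETS[self.environment]
        return tuple(self.environment)


def load_and_validate_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML/JSON config file, applying defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError([f"config root must be a mapping, got {type(raw).__name__}"])
    try:
        return ExperimentConfig(**raw)
    except ValidationError as err:
        problems = [
            f"{'.'.join(str(x) for x in e['loc']) or '(root)'}: {e['msg']}"
            for e in err.errors()
        ]
        raise ConfigError(problems) from err
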