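"""Validated run configuration for the command-line pipeline.

A single YAML (or JSON) document configures generation, simulation and
fitting.  Unknown keys are rejected so typos fail loudly; CLI flags
(--seed, --out-dir, --log-level) override the corresponding config keys.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .kinetic_core import (
    ArrheniusParams,
    KineticParameters,
    T_REF,
    VantHoffParams,
)
from .simulator import DEFAULT_TIMES_MIN
from .synthetic_data import NOISE_KINDS, NoiseModel


class ParametersConfig(BaseModel):
    """Kinetic parameter block (defaults: the reference estimates)."""

    model_config = ConfigDict(extra="forbid")

    ln_k_ref: float = 9.74
    ea_over_RTref: float = 21.4
    K_ref: float = Field(0.536, gt=0)
    dH_r: float = 34578.0
    K1: float = Field(4029.99, ge=0)
    T_ref: float = Field(T_REF, gt=0)

    def to_kinetic_parameters(self) -> KineticParameters:
        return KineticParameters(
            arrhenius=ArrheniusParams(self.ln_k_ref, self.ea_over_RTref,
                                      self.T_ref),
            vant_hoff=VantHoffParams(self.K_ref, self.dH_r, self.T_ref),
            K1=self.K1,
        )


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal[NOISE_KINDS] = "multiplicative-gaussian"
    cv_or_sd: float = Field(0.02, ge=0)

    def to_noise_model(self, seed: int) -> NoiseModel:
        return NoiseModel(kind=self.kind, cv_or_sd=self.cv_or_sd, seed=seed)


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fixed: list[str] = Field(default_factory=lambda: ["K1"])
    include_t0: bool = True
    #: optional explicit initial guess; defaults to the parameters block
    init: Optional[ParametersConfig] = None


class RunConfig(BaseModel):
    """Top-level configuration tree."""

    model_config = ConfigDict(extra="forbid")

    parameters: ParametersConfig = Field(default_factory=ParametersConfig)
    #: "default" for the built-in nine-run matrix, else a design CSV path
    design: str = "default"
    times_min: list[float] = Field(
        default_factory=lambda: list(DEFAULT_TIMES_MIN))
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    replicates: int = Field(1, ge=1)
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML/JSON config file and apply CLI overrides (highest wins)."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            data = loaded
    for key, value in overrides.items():
        if value is not None:
            data[key] = value
    return RunConfig.model_validate(data)
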