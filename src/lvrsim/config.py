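"""Validated run configuration (YAML/JSON) for the command-line tool.

The schema is strict: unknown keys are rejected before any computation.
Units follow the library conventions — pressures in cm H2O, lengths in cm,
per-alveolus volumes in microliters, whole-lung volumes in liters; depth
intervals are measured from the apex downward.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import AlveolarParams
from .scenarios import (
    ScenarioSpec,
    TreatmentSpec,
    emphysema_preset,
    healthy_preset,
)
from .sensitivity import SWEEP_PARAMETERS

__all__ = ["RunConfig", "load_config", "ConfigError"]

PRESETS = {"healthy": healthy_preset, "emphysema": emphysema_preset}


class ConfigError(ValueError):
    """Configuration failed validation."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScenarioConfig(_StrictModel):
    """Inline scenario definition (alternative to a preset name)."""

    name: str = "custom"
    height_cm: float = Field(gt=0)
    n_total: float = Field(ge=0)
    v_max_ul: float = Field(gt=0)
    v_min_ul: float = Field(ge=0)
    k_per_cmh2o: float = Field(gt=0)
    p_tlc_apex_cmh2o: float
    p_rv_apex_cmh2o: float | None = None
    p_tm_cmh2o: float = Field(ge=0)
    rho_frac: float = Field(default=0.25, ge=0, le=1)
    n_layers: int = Field(default=350, ge=1)

    def build(self) -> ScenarioSpec:
        return ScenarioSpec(
            name=self.name,
            height=self.height_cm,
            n_total=self.n_total,
            params=AlveolarParams(self.v_max_ul, self.v_min_ul, self.k_per_cmh2o),
            p_tlc_apex=self.p_tlc_apex_cmh2o,
            p_rv_apex=self.p_rv_apex_cmh2o,
            p_tm=self.p_tm_cmh2o,
            rho_frac=self.rho_frac,
            n_layers=self.n_layers,
        )


class TreatmentConfig(_StrictModel):
    """One volume-reduction arm. ``region`` is [z_lo, z_hi) cm from the
    apex, or the shorthand "upper"/"lower" for the apical/basal half."""

    region: Union[Literal["upper", "lower"], tuple[float, float]]
    n_removed: float = Field(ge=0)
    p_tlc_apex_post_cmh2o: float
    p_tm_post_cmh2o: float = Field(ge=0)
    height_post_cm: float = Field(gt=0)
    p_rv_apex_post_cmh2o: float | None = None

    def build(self, scenario: ScenarioSpec) -> TreatmentSpec:
        if self.region == "upper":
            region = (0.0, scenario.height / 2)
        elif self.region == "lower":
            region = (scenario.height / 2, scenario.height)
        else:
            region = tuple(self.region)
        return TreatmentSpec(
            region=region,
            n_removed=self.n_removed,
            p_tlc_apex_post=self.p_tlc_apex_post_cmh2o,
            p_tm_post=self.p_tm_post_cmh2o,
            height_post=self.height_post_cm,
            p_rv_apex_post=self.p_rv_apex_post_cmh2o,
        )


class TreatmentBlock(_StrictModel):
    ult: TreatmentConfig
    llt: TreatmentConfig

    @model_validator(mode="after")
    def _matched_arms(self) -> "TreatmentBlock":
        if self.ult.n_removed != self.llt.n_removed:
            raise ValueError("ult and llt arms must remove the same number of alveoli")
        return self


class CalibrationConfig(_StrictModel):
    """Anchors for the free degrees of freedom; either may be omitted."""

    rv_tlc: float | None = Field(default=None, gt=0)
    rv_liters: float | None = Field(default=None, gt=0)
    tolerance: float = Field(default=1e-6, gt=0)


class SweepConfig(_StrictModel):
    parameters: tuple[str, ...] = SWEEP_PARAMETERS
    span: float = Field(default=0.25, ge=0)
    points: int = Field(default=3, ge=2)
    mode: Literal["one_at_a_time", "joint"] = "one_at_a_time"
    dominance: bool = False

    @model_validator(mode="after")
    def _known_parameters(self) -> "SweepConfig":
        unknown = set(self.parameters) - set(SWEEP_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown sweep parameters {sorted(unknown)}")
        return self


class RunConfig(_StrictModel):
    """Top-level configuration for every command."""

    scenario: Union[Literal["healthy", "emphysema"], ScenarioConfig]
    calibration: CalibrationConfig | None = None
    treatment: TreatmentBlock | None = None
    sweep: SweepConfig | None = None
    plots: bool = False
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"

    def build_scenario(self) -> ScenarioSpec:
        """Resolve the scenario, applying any calibration block."""
        if isinstance(self.scenario, str):
            scenario = PRESETS[self.scenario]()
        else:
            scenario = self.scenario.build()
        if self.calibration is not None:
            from .calibration import calibrate_scenario

            scenario = calibrate_scenario(
                scenario,
                rv_tlc=self.calibration.rv_tlc,
                rv_liters=self.calibration.rv_liters,
                tolerance=self.calibration.tolerance,
            )
        return scenario


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) config file."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
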