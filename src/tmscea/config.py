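"""Configuration loading and validation.

The unit-cost/configuration file is YAML or JSON and carries the model
settings, the per-arm intervention cost inputs, mortality inputs and the
societal-perspective scalars. All money is GBP at the stated costing
year. Unknown keys are rejected; simple unit/range checks run at load
time and report the offending key path.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .econ import InterventionCostInputs
from .engine import ModelSettings

__all__ = ["Config", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SettingsConfig(_Strict):
    cycle_length_weeks: float = Field(2.0, gt=0)
    horizon_cycles: int = Field(39, gt=0)
    annual_discount_rate: float = Field(0.035, ge=0, le=0.2)
    cycles_per_year: float = Field(26.0, gt=0)
    half_cycle_correction: bool = True

    def to_settings(self) -> ModelSettings:
        return ModelSettings(**self.model_dump())


class InterventionConfig(_Strict):
    equipment_capital_gbp: float = Field(gt=0)
    equipment_lifetime_years: float = Field(10.0, gt=0)
    throughput_per_year: float = Field(43.0, ge=1)
    sessions_per_course: float = Field(27.0, gt=0)
    minutes_per_session: float = Field(30.0, gt=0)
    staff_cost_per_hour_gbp: float = Field(gt=0)
    training_cost_per_course_gbp: float = Field(0.0, ge=0)
    imaging_cost_gbp: float = Field(0.0, ge=0)
    discount_rate: float = Field(0.035, ge=0)

    def to_inputs(self) -> InterventionCostInputs:
        return InterventionCostInputs(
            equipment_capital=self.equipment_capital_gbp,
            equipment_lifetime_years=self.equipment_lifetime_years,
            throughput_per_year=self.throughput_per_year,
            sessions_per_course=self.sessions_per_course,
            minutes_per_session=self.minutes_per_session,
            staff_cost_per_hour=self.staff_cost_per_hour_gbp,
            training_cost_per_course=self.training_cost_per_course_gbp,
            imaging_cost=self.imaging_cost_gbp,
            discount_rate=self.discount_rate,
        )


class MortalityConfig(_Strict):
    annual_mortality: float = Field(0.0025, ge=0, lt=1)
    relative_risk: float = Field(1.58, gt=0)
    cohort_age: float = Field(45.0, ge=18, le=90)
    cohort_female_fraction: float = Field(0.55, ge=0, le=1)


class SocietalConfig(_Strict):
    daily_earnings_gbp: float = Field(120.0, gt=0)
    employed_fraction: float = Field(0.55, ge=0, le=1)


class Config(_Strict):
    currency: str = "GBP"
    costing_year: str = "2022/23"
    placeholder_values: bool = True  # unit costs stand in for unpublished ones
    settings: SettingsConfig = SettingsConfig()
    intervention_rtms: InterventionConfig
    intervention_itbs: InterventionConfig
    mortality: MortalityConfig = MortalityConfig()
    societal: SocietalConfig = SocietalConfig()
    n_sims: int = Field(5000, gt=0)

    @field_validator("currency")
    @classmethod
    def _gbp_only(cls, v: str) -> str:
        if v != "GBP":
            raise ValueError("all money must be expressed in GBP")
        return v


def load_config(path: str | Path) -> Config:
    """Load and schema-validate a YAML/JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return Config.model_validate(data)


def dump_config(config: Config, path: str | Path) -> Path:
    """Write a configuration back to YAML (round-trip stable)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
    return path
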