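"""Run configuration: schema, validation, defaults, and provenance echo.

A run is fully described by a YAML or JSON document with three sections
(``model``, ``economics``, ``sensitivity``) plus an output directory.  Every
field has a default equal to the base-case parameterization, so an empty
document is a valid run.  Validation happens before any computation: unknown
keys are rejected with their paths, and all violations are reported together.
A normalized echo of the effective configuration is written alongside results
for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from . import __version__
from .economics import DEFAULT_WTP
from .engine import CycleEconomics, MarkovSpec
from .sensitivity import ParamRange
from .survival import (
    LifeTable,
    ParametricSurvival,
    ValidationError,
    calibrate_exponential_from_median,
    read_life_table_csv,
)
from .synthetic import (
    DEFAULT_PS_DEATH_MEDIAN_MONTHS,
    base_case_ranges,
    gen_life_table,
)

__all__ = ["RunConfig", "validate_config", "load_config", "build_inputs", "write_config_echo"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SurvivalLawConfig(_Section):
    family: Literal["weibull", "gompertz", "exponential"]
    scale_lambda: float = Field(gt=0)
    shape_gamma: float = 1.0
    time_unit: Literal["month", "quarter", "year"] = "month"

    def build(self) -> ParametricSurvival:
        return ParametricSurvival(self.family, self.scale_lambda, self.shape_gamma, self.time_unit)


class LifeTableConfig(_Section):
    csv_path: Optional[str] = None        # columns age, annual_death_prob
    starting_age: int = 60
    max_age: int = 100
    base_annual_prob: float = Field(default=0.008, ge=0, le=1)
    annual_growth: float = Field(default=0.08, ge=0)


class ModelSection(_Section):
    starting_age: float = 60
    horizon_cycles: int = Field(default=240, ge=1)
    cycle_length_months: float = Field(default=1.0, gt=0)
    treated_strategy: str = "osimertinib"
    force_all_dead_at_horizon: bool = True
    half_cycle_correction: bool = False
    ps_death_median_months: float = Field(default=DEFAULT_PS_DEATH_MEDIAN_MONTHS, gt=0)
    ps_death_model: Optional[SurvivalLawConfig] = None   # overrides the median calibration
    dfs_survival: dict[str, SurvivalLawConfig] = Field(
        default_factory=lambda: {
            "osimertinib": SurvivalLawConfig(
                family="weibull", scale_lambda=0.000112076, shape_gamma=2.162643
            ),
            "placebo": SurvivalLawConfig(
                family="gompertz", scale_lambda=0.0131044, shape_gamma=0.425736
            ),
        }
    )
    life_table: LifeTableConfig = Field(default_factory=LifeTableConfig)


class EconomicsSection(_Section):
    drug_cost_per_cycle: float = Field(default=858.46, ge=0)
    followup_cost_per_cycle: float = Field(default=60.3, ge=0)
    supportive_care_cost_per_cycle: float = Field(default=359.0, ge=0)
    sae_cost_per_event: float = Field(default=362.0, ge=0)
    sae_probability: float = Field(default=0.23, ge=0, le=1)
    utility_dfs: float = Field(default=0.82, ge=0, le=1)
    utility_ps: float = Field(default=0.70, ge=0, le=1)
    sae_disutility: float = Field(default=-0.0731, le=0)
    treatment_cap_cycles: int = Field(default=36, ge=0)
    discount_rate_cost: float = Field(default=0.05, ge=0)
    discount_rate_outcome: float = Field(default=0.05, ge=0)
    drug_cost_in_ps: bool = False


class RangeConfig(_Section):
    path: str
    base: float
    low: float
    high: float
    distribution: Literal["beta", "gamma", "uniform", "fixed"] = "fixed"
    negated: bool = False

    def build(self) -> ParamRange:
        return ParamRange(self.path, self.base, self.low, self.high, self.distribution, self.negated)


class SensitivitySection(_Section):
    seed: int = 20220611
    n_iterations: int = Field(default=1000, ge=1)
    wtp_threshold: float = Field(default=DEFAULT_WTP, ge=0)
    wtp_grid_max: float = Field(default=DEFAULT_WTP, gt=0)
    wtp_grid_step: float = Field(default=1000.0, gt=0)
    ranges: Optional[list[RangeConfig]] = None   # None -> base-case ranges


class RunConfig(_Section):
    """Validated, fully-defaulted description of one analysis run."""

    model: ModelSection = Field(default_factory=ModelSection)
    economics: EconomicsSection = Field(default_factory=EconomicsSection)
    sensitivity: SensitivitySection = Field(default_factory=SensitivitySection)
    output_dir: str = "results"

    def wtp_grid(self) -> list[float]:
        import numpy as np

        g = np.arange(0.0, self.sensitivity.wtp_grid_max + self.sensitivity.wtp_grid_step, self.sensitivity.wtp_grid_step)
        return [float(x) for x in g]


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw mapping into a :class:`RunConfig`.

    All violations are reported at once, each with its field path; unknown
    keys are rejected.
    """
    try:
        return RunConfig.model_validate(raw or {})
    except PydanticValidationError as exc:
        msgs = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ValidationError("invalid configuration:\n  " + "\n  ".join(msgs)) from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON configuration file."""
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)  # YAML is a JSON superset, so this covers both
    if raw is not None and not isinstance(raw, dict):
        raise ValidationError(f"{path}: configuration root must be a mapping")
    return validate_config(raw)


def build_inputs(cfg: RunConfig) -> tuple[MarkovSpec, CycleEconomics, list[ParamRange]]:
    """Materialize the validated configuration into model objects."""
    m = cfg.model
    if m.ps_death_model is not None:
        ps_model = m.ps_death_model.build()
    else:
        ps_model = calibrate_exponential_from_median(m.ps_death_median_months)
    lt_cfg = m.life_table
    if lt_cfg.csv_path:
        table: LifeTable = read_life_table_csv(lt_cfg.csv_path)
    else:
        table = gen_life_table(
            starting_age=lt_cfg.starting_age,
            max_age=lt_cfg.max_age,
            base_annual_prob=lt_cfg.base_annual_prob,
            annual_growth=lt_cfg.annual_growth,
        )
    spec = MarkovSpec(
        dfs_survival={k: v.build() for k, v in m.dfs_survival.items()},
        ps_death_model=ps_model,
        life_table=table,
        starting_age=m.starting_age,
        horizon_cycles=m.horizon_cycles,
        cycle_length_months=m.cycle_length_months,
        treated_strategy=m.treated_strategy,
        force_all_dead_at_horizon=m.force_all_dead_at_horizon,
        half_cycle_correction=m.half_cycle_correction,
    )
    econ = CycleEconomics(**cfg.economics.model_dump())
    if cfg.sensitivity.ranges is None:
        ranges = base_case_ranges()
    else:
        ranges = [r.build() for r in cfg.sensitivity.ranges]
    return spec, econ, ranges


def write_config_echo(cfg: RunConfig, out_dir) -> Path:
    """Write the normalized effective configuration next to the results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "config_echo.yaml"
    doc = {"package_version": __version__, **cfg.model_dump()}
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path
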