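"""Synthetic inputs: digitized-curve point sets, life tables, base-case fixtures.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is testable offline:

* :func:`gen_km_points` emulates the coordinates a graph digitizer reads off a
  published Kaplan-Meier figure — evaluations of a known parametric law at a
  time grid, optionally perturbed by additive read-off noise on the survival
  scale and re-monotonized.
* :func:`gen_life_table` is a synthetic stand-in for a national all-cause
  mortality schedule: a geometrically growing annual death probability.  The
  defaults give a 60-year-old roughly a 60-70% chance of surviving 20 years,
  which is demographically plausible for the cohort modelled here; it does not
  reproduce any real census table.
* :func:`base_case` returns the full published parameterization of the
  adjuvant-osimertinib cost-utility model: fitted DFS laws per arm, SAE terms,
  per-cycle costs and utilities with their sensitivity ranges, a 20-year
  monthly-cycle horizon, 5%/year discounting and the $31,451.64/QALY
  willingness-to-pay threshold (3x 2020 Chinese GDP per capita).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .economics import DEFAULT_WTP
from .engine import CycleEconomics, MarkovSpec
from .sensitivity import ParamRange
from .survival import (
    DigitizedKMCurve,
    LifeTable,
    ParametricSurvival,
    ValidationError,
    calibrate_exponential_from_median,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticKMSpec",
    "gen_km_points",
    "gen_life_table",
    "base_case",
    "base_case_ranges",
    "write_km_csv",
    "write_life_table_csv",
    "OSIMERTINIB_DFS",
    "PLACEBO_DFS",
    "DEFAULT_PS_DEATH_MEDIAN_MONTHS",
]

#: Fitted Weibull DFS law for the osimertinib arm (lambda, gamma as published).
OSIMERTINIB_DFS = ParametricSurvival("weibull", 0.000112076, 2.162643, "month")
#: Fitted Gompertz DFS law for the placebo arm (lambda, gamma as published).
#: The publication does not state the time scale of these parameters; the
#: monthly default is configurable (see docs/methods.md).
PLACEBO_DFS = ParametricSurvival("gompertz", 0.0131044, 0.425736, "month")
#: Median post-progression survival used to calibrate the exponential
#: progression-to-death law (months); a configuration default, not a
#: published value.
DEFAULT_PS_DEATH_MEDIAN_MONTHS = 38.6


@dataclass(frozen=True)
class SyntheticKMSpec:
    """Recipe for a synthetic digitized survival curve with known truth."""

    model: ParametricSurvival
    times: tuple
    jitter_sd: float = 0.0
    seed: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        if not t:
            raise ValidationError("times: time grid must be non-empty")
        if t[0] <= 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("times: must be strictly increasing and positive")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd: must be non-negative")
        object.__setattr__(self, "times", t)


def gen_km_points(spec: SyntheticKMSpec) -> DigitizedKMCurve:
    """Evaluate the generating law on the grid, jitter, clip and re-monotonize.

    With ``jitter_sd = 0`` the output reproduces the law exactly.  Jittered
    values are clipped to (0, 1] and made non-increasing by a running minimum
    (isotonic clipping), mimicking how a careful digitizer never reads a
    rising survival curve.
    """
    t = np.asarray(spec.times)
    s = np.asarray(spec.model.survival(t), dtype=float)
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        s = s + rng.normal(0.0, spec.jitter_sd, size=len(t))
        s = np.clip(s, 1e-6, 1.0)
        s = np.minimum.accumulate(s)
    return DigitizedKMCurve(times=tuple(t), survival=tuple(s), label=spec.label)


def gen_life_table(
    starting_age: int = 60,
    max_age: int = 100,
    base_annual_prob: float = 0.008,
    annual_growth: float = 0.08,
) -> LifeTable:
    """Geometric-growth annual mortality: ``q(age) = base * (1+g)^(age-start)``.

    Probabilities are clipped at 1 (with a warning) if the growth drives them
    past it before ``max_age``.
    """
    if max_age < starting_age:
        raise ValidationError("max_age: must be >= starting_age")
    if not 0.0 <= base_annual_prob <= 1.0:
        raise ValidationError("base_annual_prob: must lie in [0, 1]")
    ages = np.arange(starting_age, max_age + 1)
    q = base_annual_prob * (1.0 + annual_growth) ** (ages - starting_age)
    if np.any(q > 1.0):
        logger.warning(
            "life-table growth drives annual death probability above 1 before "
            "age %d; clipping", max_age,
        )
        q = np.minimum(q, 1.0)
    return LifeTable(ages=tuple(int(a) for a in ages), annual_death_prob=tuple(q))


def base_case_ranges() -> list[ParamRange]:
    """Sensitivity ranges for the base case: published (low, high) intervals.

    Distribution families follow standard practice — beta for utilities,
    probabilities and the negated SAE disutility; gamma for costs; uniform on
    0-8%/year for both discount rates (the published analysis varies them but
    prints no range).
    """
    return [
        ParamRange("economics.drug_cost_per_cycle", 858.46, 429.23, 858.46, "gamma"),
        ParamRange("economics.followup_cost_per_cycle", 60.3, 45.5, 75.1, "gamma"),
        ParamRange("economics.sae_cost_per_event", 362.0, 272.0, 453.0, "gamma"),
        ParamRange("economics.supportive_care_cost_per_cycle", 359.0, 169.0, 845.0, "gamma"),
        ParamRange("economics.utility_dfs", 0.82, 0.78, 0.86, "beta"),
        ParamRange("economics.utility_ps", 0.70, 0.66, 0.74, "beta"),
        ParamRange("economics.sae_disutility", -0.0731, -0.0731, 0.0, "beta", negated=True),
        ParamRange("economics.sae_probability", 0.23, 0.1725, 0.2875, "beta"),
        ParamRange("economics.discount_rate_cost", 0.05, 0.0, 0.08, "uniform"),
        ParamRange("economics.discount_rate_outcome", 0.05, 0.0, 0.08, "uniform"),
    ]


def base_case(
    ps_death_median_months: float = DEFAULT_PS_DEATH_MEDIAN_MONTHS,
    starting_age: int = 60,
    horizon_cycles: int = 240,
) -> tuple[MarkovSpec, CycleEconomics, list[ParamRange]]:
    """The complete base-case parameterization of the adjuvant-therapy model.

    Returns a validated ``(MarkovSpec, CycleEconomics, ranges)`` triple:
    Weibull DFS for osimertinib, Gompertz DFS for placebo, an exponential
    progression-to-death law calibrated to the supplied median, the synthetic
    life table, and the published costs/utilities/SAE terms with their
    sensitivity ranges.
    """
    spec = MarkovSpec(
        dfs_survival={"osimertinib": OSIMERTINIB_DFS, "placebo": PLACEBO_DFS},
        ps_death_model=calibrate_exponential_from_median(ps_death_median_months),
        life_table=gen_life_table(starting_age=starting_age),
        starting_age=starting_age,
        horizon_cycles=horizon_cycles,
        treated_strategy="osimertinib",
    )
    econ = CycleEconomics()  # field defaults are the published base-case values
    return spec, econ, base_case_ranges()


def write_km_csv(curve: DigitizedKMCurve, path) -> None:
    """Emit curve points in the CSV layout the fit consumer reads."""
    df = pd.DataFrame({"time": curve.times, "survival": curve.survival})
    if curve.label:
        df["label"] = curve.label
    df.to_csv(Path(path), index=False)


def write_life_table_csv(table: LifeTable, path) -> None:
    pd.DataFrame({"age": table.ages, "annual_death_prob": table.annual_death_prob}).to_csv(
        Path(path), index=False
    )
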