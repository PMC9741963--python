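"""Three-state Markov cohort engine with discounted cost/QALY accumulation.

States are disease-free survival (DFS), progressed survival (PS) and Death
(absorbing).  The whole cohort starts in DFS.  Each monthly cycle a DFS
occupant may progress (per-cycle interval probability from the strategy's DFS
survival law), die of background causes (life table), or remain; a PS occupant
may die (post-progression survival law blended with background mortality) or
remain.  Costs and QALYs are accrued per cycle on state occupancy and
discounted at annual rates compounded by cycle.

Accrual rules
-------------
* DFS occupants incur a follow-up cost every cycle, plus the drug cost while
  the treated strategy is within its treatment cap.
* PS occupants incur a supportive-care cost only; no post-progression drug
  cost by default (a config switch on :class:`CycleEconomics` enables it).
* Severe adverse events (SAEs) enter as a one-time expected-value adjustment
  at treatment start on the treated arm: probability-weighted cost, and a
  probability-weighted utility decrement lasting one cycle.
* No half-cycle correction by default (state membership is costed at cycle
  start); set ``half_cycle_correction=True`` to average start/end occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .survival import (
    LifeTable,
    ParametricSurvival,
    ValidationError,
    combine_mortality,
    interval_transition_prob,
)

__all__ = [
    "STATES",
    "MarkovSpec",
    "CycleEconomics",
    "CohortTrace",
    "ModelSpecificationError",
    "discount_factor",
    "build_transition_row",
    "transition_matrix",
    "run_cohort",
]

STATES = ("DFS", "PS", "Death")
DFS, PS, DEATH = 0, 1, 2


class ModelSpecificationError(ValueError):
    """The model specification implies an impossible transition structure."""


def discount_factor(annual_rate: float, cycle_index: int, cycles_per_year: float = 12.0) -> float:
    """Discount multiplier ``(1 + r)**(-k / cycles_per_year)`` for cycle ``k``."""
    if annual_rate < 0:
        raise ValidationError(f"annual_rate: discount rate must be non-negative, got {annual_rate}")
    return float((1.0 + annual_rate) ** (-cycle_index / cycles_per_year))


@dataclass(frozen=True)
class MarkovSpec:
    """Structural definition of the three-state cohort model.

    ``dfs_survival`` maps each strategy name to its DFS survival law;
    ``treated_strategy`` names the arm that accrues drug cost and the SAE
    adjustment.  ``ps_death_model`` drives progression-to-death; background
    mortality from ``life_table`` applies in every alive state, with age
    advancing from ``starting_age`` along model time.
    """

    dfs_survival: Mapping[str, ParametricSurvival]
    ps_death_model: ParametricSurvival
    life_table: LifeTable
    starting_age: float = 60.0
    horizon_cycles: int = 240
    cycle_length_months: float = 1.0
    treated_strategy: str = "osimertinib"
    force_all_dead_at_horizon: bool = True
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ValidationError(f"horizon_cycles: must be >= 1, got {self.horizon_cycles}")
        if self.cycle_length_months <= 0:
            raise ValidationError("cycle_length_months: must be positive")
        if not self.dfs_survival:
            raise ValidationError("dfs_survival: at least one strategy is required")
        if self.treated_strategy not in self.dfs_survival:
            raise ValidationError(
                f"treated_strategy: {self.treated_strategy!r} has no DFS survival law"
            )
        object.__setattr__(self, "dfs_survival", MappingProxyType(dict(self.dfs_survival)))

    @property
    def strategies(self) -> tuple:
        return tuple(self.dfs_survival)

    def _key(self, strategy: str):
        return (
            self.dfs_survival[strategy],
            self.ps_death_model,
            self.life_table,
            self.starting_age,
            self.horizon_cycles,
            self.cycle_length_months,
        )


@dataclass(frozen=True)
class CycleEconomics:
    """Per-cycle costs (2021 USD), utilities, SAE terms and discount rates."""

    drug_cost_per_cycle: float = 858.46
    followup_cost_per_cycle: float = 60.3
    supportive_care_cost_per_cycle: float = 359.0
    sae_cost_per_event: float = 362.0
    sae_probability: float = 0.23
    utility_dfs: float = 0.82
    utility_ps: float = 0.70
    sae_disutility: float = -0.0731
    treatment_cap_cycles: int = 36
    discount_rate_cost: float = 0.05
    discount_rate_outcome: float = 0.05
    drug_cost_in_ps: bool = False

    def __post_init__(self) -> None:
        for name in (
            "drug_cost_per_cycle",
            "followup_cost_per_cycle",
            "supportive_care_cost_per_cycle",
            "sae_cost_per_event",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: cost must be non-negative")
        for name in ("utility_dfs", "utility_ps"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name}: utility must lie in [0, 1]")
        if self.sae_disutility > 0:
            raise ValidationError("sae_disutility: must be <= 0")
        if not 0.0 <= self.sae_probability <= 1.0:
            raise ValidationError("sae_probability: must lie in [0, 1]")
        if self.treatment_cap_cycles < 0:
            raise ValidationError("treatment_cap_cycles: must be >= 0")
        for name in ("discount_rate_cost", "discount_rate_outcome"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: discount rate must be non-negative")


@dataclass
class CohortTrace:
    """Per-cycle occupancy and cost/QALY increments for one strategy."""

    strategy: str
    occupancy: np.ndarray          # (n_cycles, 3), state fractions at cycle start
    cost_undisc: np.ndarray
    cost_disc: np.ndarray
    qaly_undisc: np.ndarray
    qaly_disc: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.cost_disc)

    @property
    def total_cost(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_disc.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "p_dfs": self.occupancy[:, DFS],
                "p_ps": self.occupancy[:, PS],
                "p_death": self.occupancy[:, DEATH],
                "cost_undisc": self.cost_undisc,
                "cost_disc": self.cost_disc,
                "qaly_undisc": self.qaly_undisc,
                "qaly_disc": self.qaly_disc,
            }
        )


# Cycle-probability arrays depend only on the survival side of the spec, never
# on economics, so they are memoized: a PSA that redraws costs and utilities
# re-runs the accumulation, not the survival algebra.
_PROB_CACHE: dict = {}


def _cycle_probs(spec: MarkovSpec, strategy: str, n_cycles: int):
    """(p_progress, p_background, p_ps_death) arrays over ``n_cycles`` cycles."""
    key = (spec._key(strategy), n_cycles)
    hit = _PROB_CACHE.get(key)
    if hit is not None:
        return hit
    dt = spec.cycle_length_months
    dfs_model = spec.dfs_survival[strategy]
    k = np.arange(n_cycles)
    t0 = k * dt
    s_dfs = np.asarray(dfs_model.survival_months(np.append(t0, n_cycles * dt)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s_dfs[:-1] > 0.0, s_dfs[1:] / np.where(s_dfs[:-1] > 0, s_dfs[:-1], 1.0), 0.0)
    p_prog = np.clip(1.0 - ratio, 0.0, 1.0)

    s_ps = np.asarray(spec.ps_death_model.survival_months(np.append(t0, n_cycles * dt)))
    ratio_ps = np.where(s_ps[:-1] > 0.0, s_ps[1:] / np.where(s_ps[:-1] > 0, s_ps[:-1], 1.0), 0.0)
    p_ps_disease = np.clip(1.0 - ratio_ps, 0.0, 1.0)

    ages = spec.starting_age + np.floor(t0 / 12.0)
    p_bg = np.array([spec.life_table.cycle_prob(a, dt) for a in ages])

    p_psd = 1.0 - (1.0 - p_ps_disease) * (1.0 - p_bg)
    out = (p_prog, p_bg, p_psd)
    if len(_PROB_CACHE) > 64:
        _PROB_CACHE.clear()
    _PROB_CACHE[key] = out
    return out


def transition_matrix(spec: MarkovSpec, strategy: str, cycle_index: int) -> np.ndarray:
    """One-cycle 3x3 transition matrix (rows: from-state, columns: to-state).

    DFS competing risks are progression (from the DFS law) and background
    death; their sum exceeding 1 is a specification error, never silently
    renormalized.  Death is absorbing.
    """
    if not 0 <= cycle_index < spec.horizon_cycles:
        raise ValidationError(
            f"cycle_index: must lie in [0, {spec.horizon_cycles}), got {cycle_index}"
        )
    if strategy not in spec.dfs_survival:
        raise ValidationError(f"strategy: unknown strategy {strategy!r}")
    p_prog, p_bg, p_psd = _cycle_probs(spec, strategy, spec.horizon_cycles)
    return _matrix_at(p_prog[cycle_index], p_bg[cycle_index], p_psd[cycle_index])


def build_transition_row(spec: MarkovSpec, strategy: str, cycle_index: int, state: str = "DFS") -> np.ndarray:
    """Outgoing probability row for one state at one cycle."""
    if state not in STATES:
        raise ValidationError(f"state: {state!r} is not one of {STATES}")
    return transition_matrix(spec, strategy, cycle_index)[STATES.index(state)]


def _matrix_at(p_prog: float, p_bg: float, p_psd: float) -> np.ndarray:
    # DFS -> PS is the progression probability net of background death
    # (multiplicative competing risks), so the row is valid for any pair of
    # admissible probabilities, including a progression hazard driving
    # p_prog -> 1.  Inadmissible inputs still raise rather than renormalize.
    for name, p in (("progression", p_prog), ("background death", p_bg), ("PS death", p_psd)):
        if not 0.0 <= p <= 1.0:
            raise ModelSpecificationError(f"{name} probability {p!r} outside [0, 1]")
    return np.array(
        [
            [(1.0 - p_bg) * (1.0 - p_prog), (1.0 - p_bg) * p_prog, p_bg],
            [0.0, 1.0 - p_psd, p_psd],
            [0.0, 0.0, 1.0],
        ]
    )


_EXTINCTION_TOL = 1e-9
_EXTINCTION_CAP_FACTOR = 10


def run_cohort(spec: MarkovSpec, econ: CycleEconomics, strategy: str) -> CohortTrace:
    """Simulate the cohort for one strategy and accrue discounted cost/QALY.

    The whole cohort starts in DFS.  With ``force_all_dead_at_horizon`` (the
    default) accrual stops at the horizon and any residual alive fraction
    contributes nothing beyond the final cycle; otherwise the run continues
    past the horizon until the cohort is extinct (capped at 10x horizon).
    """
    if strategy not in spec.dfs_survival:
        raise ValidationError(f"strategy: unknown strategy {strategy!r}")
    n = spec.horizon_cycles
    n_max = n if spec.force_all_dead_at_horizon else n * _EXTINCTION_CAP_FACTOR
    p_prog, p_bg, p_psd = _cycle_probs(spec, strategy, n_max)

    treated = strategy == spec.treated_strategy
    cpy = 12.0 / spec.cycle_length_months          # cycles per year
    yrs_per_cycle = spec.cycle_length_months / 12.0
    dfc = (1.0 + econ.discount_rate_cost) ** (-np.arange(n_max) / cpy)
    dfo = (1.0 + econ.discount_rate_outcome) ** (-np.arange(n_max) / cpy)

    occ = np.zeros((n_max + 1, 3))
    occ[0, DFS] = 1.0
    cost_u = np.zeros(n_max)
    qaly_u = np.zeros(n_max)

    last = n_max
    for k in range(n_max):
        m = _matrix_at(p_prog[k], p_bg[k], p_psd[k])
        occ[k + 1] = occ[k] @ m
        w = 0.5 * (occ[k] + occ[k + 1]) if spec.half_cycle_correction else occ[k]

        dfs_cost = econ.followup_cost_per_cycle
        if treated and k < econ.treatment_cap_cycles:
            dfs_cost += econ.drug_cost_per_cycle
        ps_cost = econ.supportive_care_cost_per_cycle
        if econ.drug_cost_in_ps:
            ps_cost += econ.drug_cost_per_cycle
        cost_u[k] = w[DFS] * dfs_cost + w[PS] * ps_cost
        qaly_u[k] = (w[DFS] * econ.utility_dfs + w[PS] * econ.utility_ps) * yrs_per_cycle
        if k == 0 and treated:
            cost_u[k] += econ.sae_probability * econ.sae_cost_per_event
            qaly_u[k] += econ.sae_probability * econ.sae_disutility * yrs_per_cycle

        if not spec.force_all_dead_at_horizon and k + 1 >= n and occ[k + 1, DEATH] > 1.0 - _EXTINCTION_TOL:
            last = k + 1
            break

    occ = occ[:last]
    cost_u, qaly_u = cost_u[:last], qaly_u[:last]
    dfc, dfo = dfc[:last], dfo[:last]

    sums = occ.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-12):
        raise ModelSpecificationError("occupancy does not sum to 1 within 1e-12")
    if np.any(np.diff(occ[:, DEATH]) < -1e-15):
        raise ModelSpecificationError("death occupancy is not non-decreasing")

    return CohortTrace(
        strategy=strategy,
        occupancy=occ,
        cost_undisc=cost_u,
        cost_disc=cost_u * dfc,
        qaly_undisc=qaly_u,
        qaly_disc=qaly_u * dfo,
    )
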