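"""Parametric survival laws and their conversion to Markov transition probabilities.

The cohort engine is driven entirely by survival functions: a parametric law
for disease-free survival (DFS) per strategy, a post-progression survival law,
and an age-indexed life table for background (all-cause) mortality.  This
module provides the three supported families (Weibull, Gompertz, exponential),
per-cycle interval transition probabilities, independent-competing-risk
blending of disease and background mortality, and recovery of parameters from
digitized Kaplan-Meier curve points.

Parameterizations
-----------------
Weibull      S(t) = exp(-lam * t**gam),            hazard h(t) = lam*gam*t**(gam-1)
Gompertz     S(t) = exp(-(lam/gam) * (exp(gam*t) - 1)),  hazard h(t) = lam*exp(gam*t)
Exponential  S(t) = exp(-lam*t),                   hazard h(t) = lam

``t`` is expressed in the law's own time unit (month, quarter or year); the
engine works in months and converts through :attr:`ParametricSurvival.months_per_unit`.
Published parameter tables frequently omit the time scale, so the unit is an
explicit, user-controllable field (see :func:`select_time_unit`).
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "FitError",
    "ParametricSurvival",
    "LifeTable",
    "DigitizedKMCurve",
    "survival_at",
    "interval_transition_prob",
    "combine_mortality",
    "fit_parametric",
    "FitDiagnostics",
    "calibrate_exponential_from_median",
    "select_time_unit",
    "read_km_csv",
    "read_life_table_csv",
]

FAMILIES = ("weibull", "gompertz", "exponential")
MONTHS_PER_UNIT = {"month": 1.0, "quarter": 3.0, "year": 12.0}


class ValidationError(ValueError):
    """An input violates a model invariant; the message names the offending field."""


class FitError(RuntimeError):
    """Curve fitting failed (too few usable points, or optimizer non-convergence)."""


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival law with an explicit time unit.

    Parameters
    ----------
    family
        One of ``"weibull"``, ``"gompertz"``, ``"exponential"``.
    scale_lambda
        Hazard-scale parameter lambda; must be positive.
    shape_gamma
        Shape parameter gamma.  Ignored for the exponential family; must be
        positive for Weibull.  A Gompertz with gamma == 0 is treated as its
        exponential limit.
    time_unit
        The unit ``t`` is measured in: ``"month"``, ``"quarter"`` or ``"year"``.
    """

    family: str
    scale_lambda: float
    shape_gamma: float = 1.0
    time_unit: str = "month"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"family: {self.family!r} is not one of {FAMILIES}")
        if not (self.scale_lambda > 0 and math.isfinite(self.scale_lambda)):
            raise ValidationError(
                f"scale_lambda: must be a positive finite real, got {self.scale_lambda}"
            )
        if not math.isfinite(self.shape_gamma):
            raise ValidationError(f"shape_gamma: must be finite, got {self.shape_gamma}")
        if self.family == "weibull" and self.shape_gamma <= 0:
            raise ValidationError(
                f"shape_gamma: Weibull shape must be positive, got {self.shape_gamma}"
            )
        if self.time_unit not in MONTHS_PER_UNIT:
            raise ValidationError(
                f"time_unit: {self.time_unit!r} is not one of {tuple(MONTHS_PER_UNIT)}"
            )

    @property
    def months_per_unit(self) -> float:
        return MONTHS_PER_UNIT[self.time_unit]

    def survival(self, t):
        """S(t) with ``t`` in the law's native time unit (scalar or array)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValidationError("t: survival time must be non-negative")
        lam, gam = self.scale_lambda, self.shape_gamma
        if self.family == "weibull":
            out = np.exp(-lam * np.power(t, gam))
        elif self.family == "exponential":
            out = np.exp(-lam * t)
        else:  # gompertz; expm1 keeps the gamma -> 0 limit numerically exact
            if gam == 0.0:
                out = np.exp(-lam * t)
            else:
                out = np.exp(-(lam / gam) * np.expm1(gam * t))
        return out if out.ndim else float(out)

    def survival_months(self, t_months):
        """S evaluated at a time given in months, regardless of native unit."""
        return self.survival(np.asarray(t_months, dtype=float) / self.months_per_unit)

    def median(self) -> float:
        """Median survival time in the law's native unit (may be inf)."""
        lam, gam = self.scale_lambda, self.shape_gamma
        ln2 = math.log(2.0)
        if self.family == "weibull":
            return (ln2 / lam) ** (1.0 / gam)
        if self.family == "exponential" or gam == 0.0:
            return ln2 / lam
        arg = 1.0 + gam * ln2 / lam
        if arg <= 0:  # defective Gompertz (gam < 0): plateau above 1/2
            return math.inf
        return math.log(arg) / gam

    def median_months(self) -> float:
        return self.median() * self.months_per_unit


def survival_at(model: ParametricSurvival, t) -> float:
    """Survival fraction S(t), ``t`` in the model's native time unit."""
    return model.survival(t)


def interval_transition_prob(
    model: ParametricSurvival, cycle_start: float, cycle_len: float
) -> float:
    """Probability of the event during ``[cycle_start, cycle_start + cycle_len)``.

    Standard conditional conversion ``p = 1 - S(t+dt)/S(t)``; times are in
    months and are converted to the model's native unit internally.  If the
    survival function has already reached zero at ``cycle_start`` the cohort is
    exhausted and the probability is defined as 1 (logged once per process).
    """
    if cycle_len < 0:
        raise ValidationError("cycle_len: must be non-negative")
    s0 = model.survival_months(cycle_start)
    if s0 == 0.0:
        _warn_exhausted()
        return 1.0
    s1 = model.survival_months(cycle_start + cycle_len)
    return float(min(1.0, max(0.0, 1.0 - s1 / s0)))


_exhausted_warned = False


def _warn_exhausted() -> None:
    global _exhausted_warned
    if not _exhausted_warned:
        logger.warning(
            "survival already zero at cycle start; transition probability set to 1"
        )
        _exhausted_warned = True


def combine_mortality(p_disease: float, p_background: float) -> float:
    """Combine two competing monthly death probabilities assuming independence.

    ``1 - (1 - p_disease) * (1 - p_background)``: commutative and never below
    either input.
    """
    for name, p in (("p_disease", p_disease), ("p_background", p_background)):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"{name}: probability must lie in [0, 1], got {p}")
    return 1.0 - (1.0 - p_disease) * (1.0 - p_background)


def calibrate_exponential_from_median(
    median_survival: float, time_unit: str = "month"
) -> ParametricSurvival:
    """Exponential law with rate ``ln 2 / median`` so that S(median) = 1/2."""
    if not (median_survival > 0 and math.isfinite(median_survival)):
        raise ValidationError(
            f"median_survival: must be a positive finite time, got {median_survival}"
        )
    return ParametricSurvival(
        family="exponential",
        scale_lambda=math.log(2.0) / median_survival,
        time_unit=time_unit,
    )


def select_time_unit(
    family: str,
    scale_lambda: float,
    shape_gamma: float,
    target_median_months: float,
) -> str:
    """Pick the time unit whose implied median survival best matches a target.

    Digitized-curve parameter tables often omit the time scale.  Given a trial
    median (in months), return the unit among month/quarter/year minimizing the
    absolute gap between the law's implied median and the target.
    """
    if not target_median_months > 0:
        raise ValidationError("target_median_months: must be positive")
    best, best_gap = None, math.inf
    for unit in MONTHS_PER_UNIT:
        m = ParametricSurvival(family, scale_lambda, shape_gamma, unit).median_months()
        gap = abs(m - target_median_months)
        if gap < best_gap:
            best, best_gap = unit, gap
    return best


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual all-cause death probabilities.

    Lookup below the first age clamps to the first entry, beyond the last age
    to the last.  Annual probabilities convert to a cycle of ``m`` months as
    ``1 - (1 - q)**(m/12)``.
    """

    ages: tuple
    annual_death_prob: tuple

    def __post_init__(self) -> None:
        ages = tuple(int(a) for a in self.ages)
        probs = tuple(float(q) for q in self.annual_death_prob)
        if len(ages) != len(probs) or not ages:
            raise ValidationError("ages/annual_death_prob: must be equal-length, non-empty")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError("ages: must be strictly increasing")
        if any(not 0.0 <= q <= 1.0 for q in probs):
            raise ValidationError("annual_death_prob: entries must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "annual_death_prob", probs)

    def annual_prob(self, age: float) -> float:
        idx = int(np.clip(np.searchsorted(self.ages, age, side="right") - 1, 0, len(self.ages) - 1))
        return self.annual_death_prob[idx]

    def cycle_prob(self, age: float, cycle_length_months: float = 1.0) -> float:
        q = self.annual_prob(age)
        return 1.0 - (1.0 - q) ** (cycle_length_months / 12.0)


@dataclass(frozen=True)
class DigitizedKMCurve:
    """Survival-curve coordinates read off a published Kaplan-Meier figure."""

    times: tuple
    survival: tuple
    label: str = ""

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        s = tuple(float(x) for x in self.survival)
        if len(t) != len(s) or not t:
            raise ValidationError("times/survival: must be equal-length, non-empty")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("times: must be strictly increasing")
        if any(b > a + 1e-12 for a, b in zip(s, s[1:])):
            raise ValidationError("survival: fractions must be non-increasing")
        if any(not 0.0 <= x <= 1.0 for x in s):
            raise ValidationError("survival: fractions must lie in [0, 1]")
        if t[0] < 0:
            raise ValidationError("times: must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)


@dataclass(frozen=True)
class FitDiagnostics:
    rmse: float
    n_points: int
    status: str = "converged"


def _clean_points(curve: DigitizedKMCurve):
    # S = 1 breaks the log(-log) transform; time ties keep the lower survival.
    by_time: dict = {}
    for t, s in zip(curve.times, curve.survival):
        if t <= 0 or not (0.0 < s < 1.0):
            continue
        by_time[t] = min(s, by_time.get(t, 1.0))
    t = np.array(sorted(by_time))
    return t, np.array([by_time[x] for x in t])


def fit_parametric(
    curve: DigitizedKMCurve, family: str, time_unit: str = "month"
) -> tuple[ParametricSurvival, FitDiagnostics]:
    """Recover parametric-survival parameters from digitized curve points.

    Weibull uses the closed-form linearization (regress ``log(-log S)`` on
    ``log t``); Gompertz and exponential use bounded nonlinear least squares on
    the survival scale.  Returns the fitted law and an RMSE diagnostic on the
    survival scale.
    """
    if family not in FAMILIES:
        raise ValidationError(f"family: {family!r} is not one of {FAMILIES}")
    t, s = _clean_points(curve)
    if len(t) < 3:
        raise FitError(
            f"need at least 3 usable points with 0 < S < 1 and t > 0, got {len(t)}"
        )

    if family == "weibull":
        x, y = np.log(t), np.log(-np.log(s))
        # variance-weighted closed form: read-off noise on the survival scale
        # maps to variance ~ (S ln S)^-2 in log(-log S) space (delta method),
        # so points near S = 1 would otherwise dominate the regression
        w = (s * np.log(s)) ** 2
        w = w / w.sum()
        xb, yb = float(w @ x), float(w @ y)
        gam = float(w @ ((x - xb) * (y - yb))) / float(w @ (x - xb) ** 2)
        if gam <= 0:
            raise FitError(f"weibull linearization produced non-positive shape {gam}")
        model = ParametricSurvival("weibull", float(np.exp(yb - gam * xb)), float(gam), time_unit)
    else:
        from scipy.optimize import least_squares

        lam0 = float(np.sum(t * (-np.log(s))) / np.sum(t * t))  # LS exponential rate
        if family == "exponential":
            x0, lb, ub = [lam0], [1e-12], [np.inf]
            resid = lambda p: np.exp(-p[0] * t) - s
        else:
            x0, lb, ub = [lam0, 1e-3], [1e-12, -10.0], [np.inf, 10.0]
            resid = lambda p: np.exp(-(p[0] / p[1]) * np.expm1(p[1] * t)) - s
        res = least_squares(resid, x0=x0, bounds=(lb, ub))
        if not res.success:
            raise FitError(f"optimizer did not converge: status={res.status} {res.message}")
        if family == "exponential":
            model = ParametricSurvival("exponential", float(res.x[0]), time_unit=time_unit)
        else:
            model = ParametricSurvival("gompertz", float(res.x[0]), float(res.x[1]), time_unit)

    rmse = float(np.sqrt(np.mean((model.survival(t) - s) ** 2)))
    return model, FitDiagnostics(rmse=rmse, n_points=len(t))


# ---------------------------------------------------------------------------
# CSV interfaces


def read_km_csv(path) -> DigitizedKMCurve:
    """Read digitized curve points from CSV with columns ``time,survival[,label]``."""
    rows = _read_csv(path, required=("time", "survival"))
    label = rows[0].get("label", "") if rows else ""
    return DigitizedKMCurve(
        times=tuple(float(r["time"]) for r in rows),
        survival=tuple(float(r["survival"]) for r in rows),
        label=label or "",
    )


def read_life_table_csv(path) -> LifeTable:
    """Read a life table from CSV with columns ``age,annual_death_prob``."""
    rows = _read_csv(path, required=("age", "annual_death_prob"))
    return LifeTable(
        ages=tuple(int(float(r["age"])) for r in rows),
        annual_death_prob=tuple(float(r["annual_death_prob"]) for r in rows),
    )


def _read_csv(path, required: Sequence[str]) -> list[dict]:
    text = Path(path).read_text(encoding="utf-8")
    reader = csv.DictReader(io.StringIO(text))
    missing = [c for c in required if c not in (reader.fieldnames or [])]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    return list(reader)
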