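"""Deterministic and probabilistic sensitivity analysis, tornado and CEAC.

One-way deterministic sensitivity analysis (DSA) re-runs the full model twice
per parameter (at its low and high value, all else at base) and orders
parameters by the width of the ICER swing (tornado diagram).  Probabilistic
sensitivity analysis (PSA) redraws all uncertain parameters jointly from
assigned distributions and re-runs both arms per draw; the cost-effectiveness
acceptability curve (CEAC) reports, at each willingness-to-pay value, the
fraction of draws in which the intervention has the higher net monetary
benefit (strict inequality; ties count as not cost-effective).

Distribution assignment follows standard cost-effectiveness practice: beta for
[0,1]-bounded quantities (utilities, probabilities, and the negated SAE
disutility), gamma for non-negative costs, uniform for discount rates.  The
(low, high) range is interpreted as an approximate 95% interval around the
base value, i.e. sd = (high - low) / (2 * 1.96), with beta/gamma
hyperparameters set by moment matching so each draw's mean equals the base
value.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .economics import DEFAULT_WTP, compute_icer
from .engine import CohortTrace, CycleEconomics, MarkovSpec, run_cohort
from .survival import ValidationError

__all__ = [
    "ParamRange",
    "TornadoEntry",
    "PSAResult",
    "one_way_dsa",
    "sample_psa_params",
    "run_psa",
    "ceac",
    "apply_param",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ParamRange:
    """An uncertain parameter: a dotted path, base/low/high, and a PSA law.

    ``path`` addresses a field of the economics inputs (``economics.<field>``)
    or the model structure (``model.<field>``).  ``distribution`` is one of
    ``beta``, ``gamma``, ``uniform`` or ``fixed``.  ``negated=True`` fits the
    distribution to the negated quantity (used for the SAE disutility, whose
    magnitude is [0,1]-bounded) and negates draws back.
    """

    path: str
    base: float
    low: float
    high: float
    distribution: str = "fixed"
    negated: bool = False

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"{self.path}: range must satisfy low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )
        if self.distribution not in ("beta", "gamma", "uniform", "fixed"):
            raise ValidationError(
                f"{self.path}: unknown distribution {self.distribution!r}"
            )
        lo, hi, base = self.low, self.high, self.base
        if self.negated:
            lo, hi, base = -self.high, -self.low, -self.base
        if self.distribution == "beta" and not (0.0 <= lo and hi <= 1.0):
            raise ValidationError(
                f"{self.path}: beta requires a [0,1]-bounded quantity, range ({lo}, {hi})"
            )
        if self.distribution == "gamma" and lo < 0:
            raise ValidationError(
                f"{self.path}: gamma requires a non-negative quantity, low {lo}"
            )
        # hyperparameters derived once, at construction
        object.__setattr__(self, "_hyper", self._derive(base, lo, hi))

    def _derive(self, base: float, lo: float, hi: float):
        sd = (hi - lo) / (2.0 * _Z95)
        if self.distribution in ("fixed",) or sd == 0.0:
            return ("fixed",)
        if self.distribution == "uniform":
            return ("uniform", lo, hi)
        var = sd * sd
        if self.distribution == "beta":
            if not 0.0 < base < 1.0 or var >= base * (1.0 - base):
                raise ValidationError(
                    f"{self.path}: beta moment-matching infeasible for "
                    f"mean {base}, sd {sd}"
                )
            nu = base * (1.0 - base) / var - 1.0
            return ("beta", base * nu, (1.0 - base) * nu)
        if base <= 0:
            raise ValidationError(f"{self.path}: gamma requires a positive mean, got {base}")
        return ("gamma", base * base / var, var / base)  # shape, scale

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        h = self._hyper
        if h[0] == "fixed":
            out = np.full(n, -self.base if self.negated else self.base)
        elif h[0] == "uniform":
            out = rng.uniform(h[1], h[2], size=n)
        elif h[0] == "beta":
            out = rng.beta(h[1], h[2], size=n)
        else:
            out = rng.gamma(h[1], h[2], size=n)
        return -out if self.negated else out


def apply_param(spec: MarkovSpec, econ: CycleEconomics, path: str, value: float):
    """Return (spec, econ) with the field addressed by ``path`` replaced."""
    section, _, name = path.partition(".")
    if section in ("economics", "econ"):
        if not hasattr(econ, name):
            raise ValidationError(f"{path}: no such economics field")
        kwargs = {name: int(round(value)) if name == "treatment_cap_cycles" else value}
        return spec, replace(econ, **kwargs)
    if section in ("model", "spec"):
        if not hasattr(spec, name):
            raise ValidationError(f"{path}: no such model field")
        return replace(spec, **{name: value}), econ
    raise ValidationError(f"{path}: path must start with 'economics.' or 'model.'")


@dataclass(frozen=True)
class TornadoEntry:
    param: str
    low_input: float
    high_input: float
    icer_at_low: Optional[float]
    icer_at_high: Optional[float]
    span: float
    error: Optional[str] = None


def _icer_value(spec, econ, intervention: str, comparator: str, wtp: float) -> Optional[float]:
    a = run_cohort(spec, econ, intervention)
    b = run_cohort(spec, econ, comparator)
    res = compute_icer(a.total_cost, a.total_qaly, b.total_cost, b.total_qaly, wtp)
    # tornado bars need a number in dominance quadrants too; the signed ratio
    # is used for span only, never reported as a standalone ICER
    return res.delta_cost / res.delta_qaly if res.delta_qaly != 0 else None


def one_way_dsa(
    spec: MarkovSpec,
    econ: CycleEconomics,
    ranges: Sequence[ParamRange],
    intervention: str = "osimertinib",
    comparator: str = "placebo",
    wtp: float = DEFAULT_WTP,
) -> list[TornadoEntry]:
    """One-way DSA: two full model runs per parameter, sorted by ICER span.

    Sorting is stable, descending in span, ties broken by parameter path;
    entries whose range makes the model invalid are flagged (``error`` set)
    and rank last rather than being dropped.
    """
    _icer_value(spec, econ, intervention, comparator, wtp)  # base case must run
    entries: list[TornadoEntry] = []
    for r in ranges:
        try:
            icers = []
            for v in (r.low, r.high):
                s2, e2 = apply_param(spec, econ, r.path, v)
                icers.append(_icer_value(s2, e2, intervention, comparator, wtp))
            lo, hi = icers
            span = abs(hi - lo) if lo is not None and hi is not None else math.nan
            entries.append(TornadoEntry(r.path, r.low, r.high, lo, hi, span))
        except (ValidationError, ValueError) as exc:
            entries.append(
                TornadoEntry(r.path, r.low, r.high, None, None, math.nan, error=str(exc))
            )
    entries.sort(key=lambda e: (-(e.span if math.isfinite(e.span) else -math.inf), e.param))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "param": [e.param for e in entries],
            "low_input": [e.low_input for e in entries],
            "high_input": [e.high_input for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "span": [e.span for e in entries],
            "error": [e.error for e in entries],
        }
    )


def sample_psa_params(ranges: Sequence[ParamRange], seed: int, n: int) -> pd.DataFrame:
    """Draw ``n`` joint parameter vectors; reproducible given (seed, n, order)."""
    if n < 1:
        raise ValidationError(f"n: must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({r.path: r.draw(rng, n) for r in ranges})


@dataclass
class PSAResult:
    """Per-iteration (cost, QALY) pairs per arm plus draw metadata."""

    seed: int
    n_iterations: int
    intervention: str
    comparator: str
    samples: pd.DataFrame          # one row per iteration, drawn parameter values
    results: pd.DataFrame          # cost/qaly per arm, deltas, quadrant; NaN rows = failed
    failures: list                 # (iteration index, error message)
    wtp_threshold: float

    @property
    def n_failed(self) -> int:
        return len(self.failures)

    def quadrant_fractions(self) -> dict:
        ok = self.results.dropna(subset=["delta_cost"])
        counts = ok["quadrant"].value_counts()
        return {q: float(counts.get(q, 0)) / max(len(ok), 1) for q in ("NE", "SE", "NW", "SW", "axis")}

    def summary(self) -> dict:
        ok = self.results.dropna(subset=["delta_cost"])
        qs = lambda col: [float(ok[col].quantile(q)) for q in (0.025, 0.975)]
        return {
            "n_iterations": self.n_iterations,
            "n_failed": self.n_failed,
            "mean_delta_cost": float(ok["delta_cost"].mean()),
            "mean_delta_qaly": float(ok["delta_qaly"].mean()),
            "ci95_delta_cost": qs("delta_cost"),
            "ci95_delta_qaly": qs("delta_qaly"),
            "quadrant_fractions": self.quadrant_fractions(),
        }


def run_psa(
    spec: MarkovSpec,
    econ: CycleEconomics,
    ranges: Sequence[ParamRange],
    seed: int,
    n: int = 1000,
    intervention: str = "osimertinib",
    comparator: str = "placebo",
    wtp: float = DEFAULT_WTP,
) -> PSAResult:
    """Monte-Carlo PSA: one joint draw per iteration, both arms re-run per draw.

    Iteration-level failures (a draw that violates a model invariant) are
    recorded with their draw and the run continues; the failure count is part
    of the result.
    """
    samples = sample_psa_params(ranges, seed, n)
    cols = {
        c: np.full(n, np.nan)
        for c in ("cost_int", "qaly_int", "cost_comp", "qaly_comp", "delta_cost", "delta_qaly")
    }
    quadrants = np.full(n, "", dtype=object)
    failures: list = []
    for i in range(n):
        try:
            s_i, e_i = spec, econ
            for r in ranges:
                s_i, e_i = apply_param(s_i, e_i, r.path, float(samples.iloc[i][r.path]))
            a = run_cohort(s_i, e_i, intervention)
            b = run_cohort(s_i, e_i, comparator)
            res = compute_icer(a.total_cost, a.total_qaly, b.total_cost, b.total_qaly, wtp)
        except (ValidationError, ValueError) as exc:
            failures.append((i, str(exc)))
            continue
        cols["cost_int"][i], cols["qaly_int"][i] = res.cost_intervention, res.qaly_intervention
        cols["cost_comp"][i], cols["qaly_comp"][i] = res.cost_comparator, res.qaly_comparator
        cols["delta_cost"][i], cols["delta_qaly"][i] = res.delta_cost, res.delta_qaly
        quadrants[i] = res.quadrant
    results = pd.DataFrame(cols)
    results["quadrant"] = quadrants
    return PSAResult(
        seed=seed,
        n_iterations=n,
        intervention=intervention,
        comparator=comparator,
        samples=samples,
        results=results,
        failures=failures,
        wtp_threshold=wtp,
    )


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """P(intervention cost-effective) over a WTP grid, by the strict NMB rule."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("wtp_grid: must be non-empty")
    if np.any(grid < 0):
        raise ValidationError("wtp_grid: thresholds must be non-negative")
    ok = psa.results.dropna(subset=["delta_cost"])
    if len(ok) == 0:
        raise ValidationError("psa: no successful iterations to evaluate")
    dq = ok["delta_qaly"].to_numpy()
    dc = ok["delta_cost"].to_numpy()
    # NMB(int) > NMB(comp)  <=>  wtp*dq - dc > 0; ties are not cost-effective
    prob = [(w * dq - dc > 0).mean() for w in grid]
    return pd.DataFrame({"wtp": grid, "probability": prob})
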