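"""Survival laws, interval transition probabilities, life tables, curve fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea import (
    DigitizedKMCurve,
    FitError,
    LifeTable,
    ParametricSurvival,
    ValidationError,
    calibrate_exponential_from_median,
    combine_mortality,
    fit_parametric,
    interval_transition_prob,
    select_time_unit,
    survival_at,
)

WEIBULL_OSI = ParametricSurvival("weibull", 0.000112076, 2.162643)


class TestSurvivalAt:
    def test_weibull_fitted_parameters_at_one_year(self):
        # exp(-lam * 12**gam); cross-checked against the numerically
        # integrated hazard lam*gam*t**(gam-1) over [0, 12]
        assert survival_at(WEIBULL_OSI, 12.0) == pytest.approx(0.9761132496268323, abs=1e-10)

    def test_weibull_agrees_with_numerically_integrated_hazard(self):
        from scipy.integrate import quad

        lam, gam = WEIBULL_OSI.scale_lambda, WEIBULL_OSI.shape_gamma
        cum_hazard, _ = quad(lambda t: lam * gam * t ** (gam - 1.0), 0.0, 12.0)
        assert survival_at(WEIBULL_OSI, 12.0) == pytest.approx(math.exp(-cum_hazard), rel=1e-9)

    def test_weibull_agrees_with_scipy_weibull_min(self):
        from scipy.stats import weibull_min

        lam, gam = 0.01, 2.0
        m = ParametricSurvival("weibull", lam, gam)
        t = np.linspace(0.5, 40, 17)
        expected = weibull_min.sf(t, c=gam, scale=lam ** (-1.0 / gam))
        np.testing.assert_allclose(m.survival(t), expected, rtol=1e-12)

    @pytest.mark.parametrize(
        "model",
        [
            WEIBULL_OSI,
            ParametricSurvival("gompertz", 0.0131044, 0.425736),
            ParametricSurvival("exponential", 0.1),
        ],
    )
    def test_survival_at_zero_is_one(self, model):
        assert survival_at(model, 0.0) == 1.0

    def test_gompertz_small_shape_reduces_to_exponential(self):
        m = ParametricSurvival("gompertz", 0.1, 1e-9)
        assert survival_at(m, 5.0) == pytest.approx(math.exp(-0.5), rel=1e-7)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError, match="t"):
            survival_at(WEIBULL_OSI, -1.0)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(family="weibull", scale_lambda=-0.1), "scale_lambda"),
            (dict(family="weibull", scale_lambda=0.0), "scale_lambda"),
            (dict(family="weibull", scale_lambda=0.1, shape_gamma=-2.0), "shape_gamma"),
            (dict(family="nope", scale_lambda=0.1), "family"),
            (dict(family="weibull", scale_lambda=0.1, time_unit="day"), "time_unit"),
        ],
    )
    def test_invalid_parameters_name_the_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            ParametricSurvival(**kwargs)

    @settings(max_examples=60, deadline=None)
    @given(
        family=st.sampled_from(["weibull", "gompertz", "exponential"]),
        lam=st.floats(1e-4, 0.5),
        gam=st.floats(0.3, 3.0),
    )
    def test_survival_non_increasing_on_dense_grid(self, family, lam, gam):
        m = ParametricSurvival(family, lam, gam)
        s = np.asarray(m.survival(np.linspace(0.0, 240.0, 481)))
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-15)
        # survival may underflow to exactly 0 at extreme t; never negative
        assert np.all((s >= 0) & (s <= 1))


class TestTimeUnits:
    def test_quarter_unit_rescales_time(self):
        month = ParametricSurvival("gompertz", 0.0131044, 0.425736, "month")
        quarter = ParametricSurvival("gompertz", 0.0131044, 0.425736, "quarter")
        assert quarter.survival_months(12.0) == pytest.approx(month.survival(4.0))
        assert quarter.median_months() == pytest.approx(3.0 * month.median_months())

    def test_select_time_unit_picks_best_matching_median(self):
        # the published placebo Gompertz implies a ~7.4-unit median; against a
        # ~20-month trial median the quarterly reading is the closest
        assert select_time_unit("gompertz", 0.0131044, 0.425736, 19.6) == "quarter"
        # the osimertinib Weibull median is ~56.6 in native units: months win
        assert select_time_unit("weibull", 0.000112076, 2.162643, 56.0) == "month"


class TestIntervalTransition:
    def test_exponential_constant_hazard(self):
        m = ParametricSurvival("exponential", 0.1)
        p = interval_transition_prob(m, 0.0, 1.0)
        assert p == pytest.approx(1.0 - math.exp(-0.1), rel=1e-12)
        for start in (5.0, 17.0, 119.0):
            assert interval_transition_prob(m, start, 1.0) == pytest.approx(p, rel=1e-12)

    def test_weibull_second_year_cycle(self):
        assert interval_transition_prob(WEIBULL_OSI, 12.0, 1.0) == pytest.approx(
            0.004558713601796716, abs=1e-9
        )

    def test_flat_segment_gives_zero(self):
        m = ParametricSurvival("exponential", 1e-300)  # numerically flat
        assert interval_transition_prob(m, 3.0, 1.0) == 0.0

    def test_exhausted_cohort_gives_one(self):
        m = ParametricSurvival("gompertz", 0.5, 1.0)  # survival underflows fast
        assert m.survival(200.0) == 0.0
        assert interval_transition_prob(m, 200.0, 1.0) == 1.0

    @settings(max_examples=60, deadline=None)
    @given(
        family=st.sampled_from(["weibull", "gompertz", "exponential"]),
        lam=st.floats(1e-4, 0.2),
        gam=st.floats(0.3, 2.5),
        k=st.integers(1, 48),
    )
    def test_chained_cycles_reproduce_survival_ratio(self, family, lam, gam, k):
        m = ParametricSurvival(family, lam, gam)
        prod = 1.0
        for i in range(k):
            prod *= 1.0 - interval_transition_prob(m, float(i), 1.0)
        ratio = m.survival(float(k)) / m.survival(0.0)
        assert prod == pytest.approx(ratio, rel=1e-12, abs=1e-12)


class TestCombineMortality:
    @pytest.mark.parametrize(
        "p_dis, p_bg, expected",
        [(0.0, 0.02, 0.02), (1.0, 0.37, 1.0), (0.1, 0.2, 0.28)],
    )
    def test_independent_competing_risks(self, p_dis, p_bg, expected):
        assert combine_mortality(p_dis, p_bg) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="p_disease"):
            combine_mortality(1.2, 0.1)
        with pytest.raises(ValidationError, match="p_background"):
            combine_mortality(0.1, -0.01)

    @settings(max_examples=100, deadline=None)
    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    def test_commutative_and_never_decreases_either_input(self, a, b):
        c = combine_mortality(a, b)
        assert c == combine_mortality(b, a)
        assert c >= max(a, b) - 1e-15
        assert c <= 1.0


class TestCalibrateExponential:
    def test_median_ln2_gives_unit_rate(self):
        m = calibrate_exponential_from_median(math.log(2.0))
        assert m.scale_lambda == pytest.approx(1.0, rel=1e-12)
        assert m.survival(math.log(2.0)) == pytest.approx(0.5, rel=1e-12)

    def test_default_post_progression_median(self):
        m = calibrate_exponential_from_median(38.6)
        assert interval_transition_prob(m, 0.0, 1.0) == pytest.approx(0.01779691143436879, abs=1e-10)

    def test_huge_median_gives_vanishing_cycle_probability(self):
        m = calibrate_exponential_from_median(1e12)
        assert interval_transition_prob(m, 0.0, 1.0) < 1e-11

    def test_non_positive_median_rejected(self):
        with pytest.raises(ValidationError, match="median"):
            calibrate_exponential_from_median(0.0)


class TestLifeTable:
    def test_lookup_clamps_beyond_last_age(self):
        lt = LifeTable(ages=(60, 61, 62), annual_death_prob=(0.01, 0.02, 0.03))
        assert lt.annual_prob(59) == 0.01
        assert lt.annual_prob(61.5) == 0.02
        assert lt.annual_prob(95) == 0.03

    def test_monthly_conversion(self):
        lt = LifeTable(ages=(60,), annual_death_prob=(0.12,))
        assert lt.cycle_prob(60, 1.0) == pytest.approx(1.0 - 0.88 ** (1.0 / 12.0), rel=1e-12)

    def test_twelve_monthly_cycles_compound_to_annual(self):
        lt = LifeTable(ages=(60,), annual_death_prob=(0.12,))
        p = lt.cycle_prob(60)
        assert 1.0 - (1.0 - p) ** 12 == pytest.approx(0.12, rel=1e-10)

    def test_invariants_enforced(self):
        with pytest.raises(ValidationError, match="ages"):
            LifeTable(ages=(60, 60), annual_death_prob=(0.1, 0.1))
        with pytest.raises(ValidationError, match="annual_death_prob"):
            LifeTable(ages=(60, 61), annual_death_prob=(0.1, 1.5))


class TestFitParametric:
    def grid(self, model, times):
        return DigitizedKMCurve(
            times=tuple(times), survival=tuple(np.asarray(model.survival(np.asarray(times))))
        )

    def test_weibull_noiseless_recovery(self):
        truth = ParametricSurvival("weibull", 0.01, 2.0)
        fitted, diag = fit_parametric(self.grid(truth, np.arange(2, 31, 2)), "weibull")
        assert fitted.scale_lambda == pytest.approx(0.01, rel=1e-4)
        assert fitted.shape_gamma == pytest.approx(2.0, rel=1e-4)
        assert diag.rmse < 1e-8

    def test_weibull_three_point_linearized_system(self):
        # (t, S) = (1, e^-0.01), (5, e^-0.25), (10, e^-1) lie exactly on
        # lam=0.01, gam=2: log(-log S) = log lam + gam log t at each point
        curve = DigitizedKMCurve(
            times=(1.0, 5.0, 10.0),
            survival=(math.exp(-0.01), math.exp(-0.25), math.exp(-1.0)),
        )
        fitted, _ = fit_parametric(curve, "weibull")
        assert fitted.scale_lambda == pytest.approx(0.01, rel=1e-10)
        assert fitted.shape_gamma == pytest.approx(2.0, rel=1e-10)

    def test_gompertz_noiseless_recovery(self):
        truth = ParametricSurvival("gompertz", 0.01, 0.05)
        fitted, _ = fit_parametric(self.grid(truth, np.arange(2, 61, 2)), "gompertz")
        assert fitted.scale_lambda == pytest.approx(0.01, rel=1e-3)
        assert fitted.shape_gamma == pytest.approx(0.05, rel=1e-3)

    def test_exponential_noiseless_recovery(self):
        truth = ParametricSurvival("exponential", 0.04)
        fitted, _ = fit_parametric(self.grid(truth, np.arange(1, 31)), "exponential")
        assert fitted.scale_lambda == pytest.approx(0.04, rel=1e-6)

    def test_two_points_rejected(self):
        curve = DigitizedKMCurve(times=(1.0, 2.0), survival=(0.9, 0.8))
        with pytest.raises(FitError, match="3"):
            fit_parametric(curve, "weibull")

    def test_leading_full_survival_points_are_dropped(self):
        truth = ParametricSurvival("weibull", 0.01, 2.0)
        times = np.arange(2, 31, 2)
        s = np.asarray(truth.survival(times))
        curve = DigitizedKMCurve(
            times=(0.5, *times), survival=(1.0, *s)  # S=1 breaks log(-log S)
        )
        fitted, _ = fit_parametric(curve, "weibull")
        assert fitted.shape_gamma == pytest.approx(2.0, rel=1e-4)

    def test_weibull_fit_consistent_with_lifelines_on_sampled_times(self):
        # independent route: draw individual event times from the law by
        # inverse transform and fit lifelines' WeibullFitter to them; both
        # routes should agree with the generating parameters
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(42)
        lam, gam = 0.01, 2.0
        u = rng.uniform(size=4000)
        durations = (-np.log(u) / lam) ** (1.0 / gam)
        wf = lifelines.WeibullFitter().fit(durations)
        # lifelines: S(t) = exp(-(t/lambda_)**rho_)
        ll_lam = wf.lambda_ ** (-wf.rho_)
        truth = ParametricSurvival("weibull", lam, gam)
        fitted, _ = fit_parametric(self.grid(truth, np.arange(2, 61, 2)), "weibull")
        assert wf.rho_ == pytest.approx(fitted.shape_gamma, rel=0.05)
        assert ll_lam == pytest.approx(fitted.scale_lambda, rel=0.15)


class TestDigitizedCurveInvariants:
    def test_rising_survival_rejected(self):
        with pytest.raises(ValidationError, match="non-increasing"):
            DigitizedKMCurve(times=(1.0, 2.0, 3.0), survival=(0.9, 0.95, 0.8))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError, match="times"):
            DigitizedKMCurve(times=(1.0, 1.0, 3.0), survival=(0.9, 0.8, 0.7))
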