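"""Logistic model, derived rate statistics and fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcpredox.errors import (
    DataConsistencyError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidParameterError,
)
from pcpredox.kinetics import (
    LogisticParams,
    TimeSeries,
    fit_logistic,
    logistic_value,
    r_squared,
    t_vmax,
    to_decrement,
    vmax,
)

params_st = st.builds(
    LogisticParams,
    a=st.floats(0.5, 500.0),
    b=st.floats(0.1, 1000.0),
    k=st.floats(0.02, 5.0),
)


class TestLogisticValue:
    def test_half_maximum_at_inflection(self):
        p = LogisticParams(5.91, 9.03, 0.21)
        assert logistic_value(p, math.log(9.03) / 0.21) == pytest.approx(
            5.91 / 2, rel=1e-12
        )

    def test_asymptote_is_capacity(self):
        p = LogisticParams(5.91, 9.03, 0.21)
        assert logistic_value(p, 1000.0) == pytest.approx(5.91, rel=1e-9)

    def test_unit_parameters_at_origin(self):
        assert logistic_value(LogisticParams(1, 1, 1), 0.0) == pytest.approx(0.5)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(InvalidParameterError):
            LogisticParams(-1.0, 1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            LogisticParams(1.0, 0.0, 1.0)

    @given(params_st)
    @settings(max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, p):
        tv = math.log(p.b) / p.k
        t = np.linspace(tv - 14 / p.k, tv + 14 / p.k, 200)
        y = logistic_value(p, t)
        assert np.all(np.diff(y) > 0)
        assert np.all((y > 0) & (y < p.a))


class TestDerivedStatistics:
    def test_control_sulfate_vmax(self):
        assert round(vmax(LogisticParams(5.91, 9.03, 0.21)), 2) == 0.31

    def test_control_iron_vmax(self):
        assert round(vmax(LogisticParams(119.74, 179.09, 0.76)), 2) == 22.75

    def test_control_sulfate_t_vmax(self):
        assert round(t_vmax(LogisticParams(5.91, 9.03, 0.21)), 2) == 10.48

    def test_control_pcp_t_vmax(self):
        assert round(t_vmax(LogisticParams(149.61, 170.26, 0.52)), 2) == 9.88

    def test_t_vmax_zero_when_b_is_one(self):
        assert t_vmax(LogisticParams(1.0, 1.0, 0.5)) == 0.0

    def test_vmax_vanishes_with_rate(self):
        assert vmax(LogisticParams(100.0, 5.0, 1e-9)) < 1e-6

    @given(params_st)
    @settings(max_examples=50, derandomize=True)
    def test_vmax_is_max_slope_and_inflection_at_half(self, p):
        """0.25*a*k equals the dense numerical maximum of dC/dt, attained
        where the curve crosses a/2."""
        tv = t_vmax(p)
        t = np.linspace(tv - 30 / p.k, tv + 30 / p.k, 20001)
        dt = t[1] - t[0]
        slope = np.gradient(np.asarray(logistic_value(p, t)), dt)
        assert slope.max() == pytest.approx(vmax(p), rel=1e-6)
        assert logistic_value(p, tv) == pytest.approx(p.a / 2, rel=1e-9)


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([0, 1, 2], [0, 1, 2]) == 1.0

    def test_mean_prediction_is_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # SS_res = 1, SS_tot = 2
        assert r_squared([0, 1, 2], [0, 1, 3]) == pytest.approx(0.5)

    def test_constant_observed_rejected(self):
        with pytest.raises(DegenerateInputError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 1.0])


class TestToDecrement:
    def test_full_depletion(self):
        ts = TimeSeries("c", "pcp", [0, 1, 2], [150.0, 75.0, 0.0])
        out = to_decrement(ts, baseline=150.0)
        assert np.allclose(out.values, [0.0, 75.0, 150.0])

    def test_constant_series_gives_zero_decrement(self):
        ts = TimeSeries("c", "sulfate", [0, 1], [5.91, 5.91])
        assert np.allclose(to_decrement(ts, baseline=5.91).values, 0.0)

    def test_default_baseline_is_first_value(self):
        ts = TimeSeries("c", "sulfate", [0, 1, 2], [100.0, 40.0, 10.0])
        assert np.allclose(to_decrement(ts).values, [0.0, 60.0, 90.0])

    def test_small_excursion_clipped_large_rejected(self):
        jitter = TimeSeries("c", "sulfate", [0, 1], [100.0, 101.0])
        assert np.allclose(to_decrement(jitter, baseline=100.0).values, 0.0)
        bad = TimeSeries("c", "sulfate", [0, 1], [100.0, 120.0])
        with pytest.raises(DataConsistencyError):
            to_decrement(bad, baseline=100.0)

    def test_accumulation_passes_through(self):
        ts = TimeSeries("c", "fe2", [0, 1], [0.0, 50.0])
        assert to_decrement(ts, accumulation=True) is ts


class TestFitLogistic:
    def test_exact_recovery_from_noiseless_data(self, noiseless_series, control_pcp_params):
        fit = fit_logistic(noiseless_series)
        p, truth = fit.params, control_pcp_params
        assert p.a == pytest.approx(truth.a, rel=1e-6)
        assert p.b == pytest.approx(truth.b, rel=1e-6)
        assert p.k == pytest.approx(truth.k, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    def test_derived_statistics_consistent_with_params(self, noiseless_series):
        fit = fit_logistic(noiseless_series)
        assert fit.vmax == pytest.approx(0.25 * fit.params.a * fit.params.k)
        assert fit.t_vmax == pytest.approx(math.log(fit.params.b) / fit.params.k)

    def test_noisy_recovery_within_tolerance(self, control_pcp_params):
        """3 replicates, sd 2 µM, fixed seed: a within 5%, k within 10%."""
        rng = np.random.default_rng(123)
        days = np.array([0.0, 3.0, 7.0, 12.0, 17.0, 22.0, 40.0])
        clean = np.asarray(logistic_value(control_pcp_params, days))
        mean3 = np.clip(
            clean + rng.normal(0.0, 2.0, size=(3, len(days))).mean(axis=0),
            0.0, None,
        )
        fit = fit_logistic(TimeSeries("c", "pcp", days, mean3))
        assert fit.params.a == pytest.approx(control_pcp_params.a, rel=0.05)
        assert fit.params.k == pytest.approx(control_pcp_params.k, rel=0.10)

    def test_fit_idempotence(self, noiseless_series):
        """Refitting the curve implied by a fit reproduces its params."""
        first = fit_logistic(noiseless_series)
        implied = noiseless_series.with_values(
            np.asarray(logistic_value(first.params, noiseless_series.times))
        )
        second = fit_logistic(implied)
        assert second.params.a == pytest.approx(first.params.a, rel=1e-8)
        assert second.params.b == pytest.approx(first.params.b, rel=1e-8)
        assert second.params.k == pytest.approx(first.params.k, rel=1e-8)

    def test_denser_grids_reduce_error(self, control_pcp_params):
        """Estimation error shrinks monotonically-ish with grid density."""
        errs = []
        for n in (5, 9, 17):
            days = np.linspace(0, 40, n)
            ts = TimeSeries(
                "c", "pcp", days, logistic_value(control_pcp_params, days)
            )
            fit = fit_logistic(ts)
            errs.append(abs(fit.params.k - control_pcp_params.k))
        assert errs[-1] <= errs[0] + 1e-12

    def test_too_few_points_rejected(self):
        ts = TimeSeries("c", "pcp", [0, 1, 2], [0.0, 1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            fit_logistic(ts)

    def test_constant_series_rejected(self):
        ts = TimeSeries("c", "pcp", [0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])
        with pytest.raises(DegenerateInputError):
            fit_logistic(ts)

    def test_lagged_saturating_curve_not_trapped(self):
        """A decrement that is zero through the lag then saturates must not
        fit as a step function (a known local minimum)."""
        days = np.array([0.0, 3.0, 7.0, 12.0, 17.0, 22.0, 40.0])
        dec = 150.0 * (1.0 - np.exp(-0.2 * np.clip(days - 3.0, 0.0, None)))
        fit = fit_logistic(TimeSeries("c", "pcp", days, dec))
        assert fit.r2 > 0.95


class TestTimeSeriesInvariants:
    def test_rejects_unequal_lengths(self):
        with pytest.raises(InvalidParameterError):
            TimeSeries("c", "pcp", [0, 1], [1.0])

    def test_rejects_non_increasing_times(self):
        with pytest.raises(InvalidParameterError):
            TimeSeries("c", "pcp", [0, 2, 1], [1.0, 2.0, 3.0])

    def test_rejects_negative_values(self):
        with pytest.raises(InvalidParameterError):
            TimeSeries("c", "pcp", [0, 1], [1.0, -2.0])
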