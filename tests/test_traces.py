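"""Tangent statistics: smoothing, phase segmentation, lag, dose-response."""

import numpy as np
import pytest

from crystagg import TurbidityTrace, WellCondition
from crystagg.traces import (
    DoseResponseModel,
    TraceAnalysisError,
    dose_response,
    endpoint_turbidity,
    segment_phases,
    smooth,
    tangent_fit,
    turbidity_soluble_correlation,
)


def _trace(t, tau):
    return TurbidityTrace(well="w", condition=WellCondition(), times=t, turbidity=tau)


class TestSmooth:
    def test_constant_trace_unchanged(self):
        t = np.arange(0, 901, 90.0)
        sm = smooth(_trace(t, np.full_like(t, 0.3)))
        assert np.allclose(sm.turbidity, 0.3, atol=1e-12)

    def test_quadratic_reproduced_exactly(self):
        """A local quadratic filter reproduces quadratics to rounding."""
        t = np.arange(0, 16201, 90.0)
        tau = 1e-9 * t ** 2 + 2e-5 * t + 0.01
        sm = smooth(_trace(t, tau))
        assert np.allclose(sm.turbidity, tau, atol=1e-9)

    def test_noisy_logistic_derivative_rmse_improves(self, make_logistic_trace):
        rng = np.random.default_rng(11)
        base = make_logistic_trace(L=1.0, k=0.002, t0=8000.0)
        noisy = base.turbidity * rng.lognormal(0.0, 0.02, base.turbidity.size)
        true_d = np.gradient(base.turbidity, base.times)
        raw_d = np.gradient(noisy, base.times)
        sm = smooth(_trace(base.times, noisy))
        sm_d = np.gradient(sm.turbidity, sm.times)
        assert (np.sqrt(np.mean((sm_d - true_d) ** 2))
                < np.sqrt(np.mean((raw_d - true_d) ** 2)))

    @pytest.mark.parametrize("window", [2, 1, 4])
    def test_bad_window_rejected(self, window):
        t = np.arange(0, 901, 90.0)
        with pytest.raises(TraceAnalysisError):
            smooth(_trace(t, t * 0.0), window=window)


class TestTangentFit:
    def test_logistic_closed_form(self, make_logistic_trace):
        """max rate = L·k/4 at t0; lag = t0 − 2/k, both exact on a logistic."""
        fit = tangent_fit(make_logistic_trace(L=1.0, k=0.02, t0=6000.0))
        assert fit.max_rate == pytest.approx(0.005, rel=5e-3)
        assert fit.lag_time == pytest.approx(5900.0, rel=5e-3)
        assert fit.t_at_max == pytest.approx(6000.0, rel=5e-3)

    def test_linear_ramp(self):
        t = np.arange(0, 16201, 90.0)
        fit = tangent_fit(_trace(t, 2e-4 * t))
        assert fit.max_rate == pytest.approx(2e-4, rel=1e-6)
        # baseline is the mean of the first three readings, so the tangent
        # (the ramp itself) crosses it one read interval in
        assert 0.0 <= fit.lag_time <= 2 * 90.0

    def test_scale_equivariance(self, make_logistic_trace):
        base = make_logistic_trace()
        scaled = _trace(base.times, 0.65 * base.turbidity)
        f0, f1 = tangent_fit(base), tangent_fit(scaled)
        assert f1.max_rate / f0.max_rate == pytest.approx(0.65, rel=1e-9)
        assert f1.lag_time == pytest.approx(f0.lag_time, abs=1e-6)

    def test_time_shift_equivariance(self, make_logistic_trace):
        f0 = tangent_fit(make_logistic_trace(t0=6000.0))
        f1 = tangent_fit(make_logistic_trace(t0=7500.0))
        assert f1.t_at_max - f0.t_at_max == pytest.approx(1500.0, abs=1.0)
        assert f1.lag_time - f0.lag_time == pytest.approx(1500.0, abs=1.0)

    def test_decreasing_trace_has_no_growth_phase(self):
        t = np.arange(0, 1801, 90.0)
        with pytest.raises(TraceAnalysisError, match="no growth"):
            tangent_fit(_trace(t, 1.0 - 1e-4 * t))

    def test_too_short_trace_rejected(self):
        t = np.arange(0, 7 * 90.0, 90.0)
        with pytest.raises(TraceAnalysisError):
            tangent_fit(_trace(t, t * 1e-4))

    def test_second_phase_rule_recovers_second_logistic(self):
        t = np.arange(0, 16201, 90.0)
        tau = (1.0 / (1.0 + np.exp(-0.01 * (t - 3000.0)))
               + 1.0 / (1.0 + np.exp(-0.01 * (t - 10000.0))))
        fit = tangent_fit(_trace(t, tau), phase_rule="second_phase")
        assert fit.n_phases == 2
        assert fit.phase_index == 1
        assert fit.max_rate == pytest.approx(0.01 / 4.0, rel=5e-3)
        assert fit.t_at_max == pytest.approx(10000.0, rel=5e-3)

    def test_second_phase_rule_falls_back_when_monophasic(self, make_logistic_trace):
        fit = tangent_fit(make_logistic_trace(), phase_rule="second_phase")
        assert fit.n_phases == 1
        assert fit.phase_index == 0


class TestSegmentPhases:
    def test_single_logistic_one_phase(self, make_logistic_trace):
        assert len(segment_phases(make_logistic_trace())) == 1

    def test_two_shifted_logistics_two_phases(self):
        t = np.arange(0, 16201, 90.0)
        tau = (1.0 / (1.0 + np.exp(-0.01 * (t - 3000.0)))
               + 1.0 / (1.0 + np.exp(-0.01 * (t - 10000.0))))
        assert len(segment_phases(_trace(t, tau))) == 2

    def test_monotone_ramp_single_phase_covering_trace(self):
        t = np.arange(0, 16201, 90.0)
        phases = segment_phases(_trace(t, 1e-4 * t))
        assert phases == [(0, len(t) - 1)]

    def test_monophasic_stays_monophasic_at_zero_noise(self, make_logistic_trace):
        for k in (0.0005, 0.002, 0.01):
            assert len(segment_phases(make_logistic_trace(k=k, t0=8000.0))) == 1


class TestEndpoint:
    def test_constant(self):
        t = np.arange(0, 901, 90.0)
        assert endpoint_turbidity(_trace(t, np.full_like(t, 0.42))) == pytest.approx(0.42)

    def test_logistic_endpoint_near_plateau(self, make_logistic_trace):
        assert endpoint_turbidity(make_logistic_trace(L=0.8)) == pytest.approx(0.8, rel=1e-3)

    def test_bad_tail_rejected(self, make_logistic_trace):
        with pytest.raises(TraceAnalysisError):
            endpoint_turbidity(make_logistic_trace(), tail_points=0)


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        sol = [0.1, 0.4, 0.7, 0.9]
        end = [1.0 - s for s in sol]
        res = turbidity_soluble_correlation(end, sol)
        assert res["r"] == pytest.approx(-1.0)
        assert res["slope"] == pytest.approx(-1.0)

    def test_model_panel_strongly_anticorrelated(self, params, fullox_condition):
        """With w_P = w_G turbidity is proportional to aggregated mass, so
        endpoint turbidity vs soluble fraction is an exact line (|r| > 0.99)."""
        from crystagg import AggregationModel

        p = params.replace(w_G=params.w_P)
        ends, sols = [], []
        for ino in (0.0, 50.0, 100.0, 250.0, 500.0):
            traj = AggregationModel.from_condition(p, fullox_condition(ino)).simulate()
            ends.append(endpoint_turbidity(traj.turbidity()))
            s = traj.final_state
            sols.append(1.0 - s.aggregated_mass / s.total_protein)
        res = turbidity_soluble_correlation(ends, sols)
        assert abs(res["r"]) > 0.99

    def test_permutation_null_mean_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rs = []
        for _ in range(200):
            rs.append(turbidity_soluble_correlation(
                y, rng.permutation(x))["r"])
        assert abs(np.mean(rs)) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(TraceAnalysisError):
            turbidity_soluble_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestDoseResponse:
    def test_flat_rates_flagged_saturated(self):
        fit = DoseResponseModel([0, 50, 100], [2.0, 2.0, 2.0]).fit()
        assert fit.saturated
        assert np.allclose(fit.normalized_rates, 1.0)

    def test_parameter_recovery_from_synthetic_rates(self):
        doses = np.array([0.0, 50.0, 100.0, 250.0])
        rates = 3.0e-4 / (1.0 + doses / 150.0)
        fit = DoseResponseModel(doses, rates).fit()
        assert fit.K_I == pytest.approx(150.0, rel=1e-4)

    def test_single_nonzero_dose_closed_form(self):
        # r = 1/(1 + 100/K) = 0.4  =>  K = 100·0.4/0.6
        fit = DoseResponseModel([0.0, 100.0], [1.0, 0.4]).fit()
        assert fit.K_I == pytest.approx(100.0 * 0.4 / 0.6, rel=1e-9)

    def test_zero_dose_required(self):
        with pytest.raises(TraceAnalysisError):
            DoseResponseModel([50.0, 100.0], [1.0, 0.5])

    def test_zero_reference_rate_rejected(self):
        with pytest.raises(TraceAnalysisError):
            DoseResponseModel([0.0, 100.0], [0.0, 0.5]).fit()

    def test_from_tangent_fits(self, make_logistic_trace):
        fits = {0.0: tangent_fit(make_logistic_trace(L=1.0)),
                100.0: tangent_fit(make_logistic_trace(L=0.65))}
        dr = dose_response(fits)
        assert dr.normalized_rates[1] == pytest.approx(0.65, rel=1e-6)
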