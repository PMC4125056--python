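"""Half-time, slope, lag, sigmoid fitting and the scaling exponent."""

import numpy as np
import pytest

from micellekin import (
    KineticTrace,
    apparent_nucleus_size,
    fit_sigmoid,
    half_time,
    lag_time,
    max_slope,
)
from micellekin.observables import TraceError


def logistic_trace(t_half=10.0, rate=1.0, plateau=1.0, t_end=30.0, n=601):
    t = np.linspace(0.0, t_end, n)
    return KineticTrace(times=t, signal=plateau / (1.0 + np.exp(-rate * (t - t_half))))


class TestKineticTrace:
    def test_rejects_unsorted_times(self):
        with pytest.raises(TraceError):
            KineticTrace(times=np.array([0.0, 2.0, 1.0]), signal=np.zeros(3))

    def test_rejects_non_finite_signal(self):
        with pytest.raises(TraceError):
            KineticTrace(times=np.arange(3.0), signal=np.array([0.0, np.nan, 1.0]))


class TestHalfTime:
    def test_symmetric_logistic_midpoint(self):
        assert half_time(logistic_trace()) == pytest.approx(10.0, abs=1e-3)

    def test_invariant_under_signal_rescaling(self):
        tr = logistic_trace()
        scaled = KineticTrace(times=tr.times, signal=123.4 * tr.signal)
        assert half_time(scaled) == pytest.approx(half_time(tr))

    def test_unconverged_trace_rejected(self):
        t = np.linspace(0, 10, 100)
        with pytest.raises(TraceError, match="plateau"):
            half_time(KineticTrace(times=t, signal=t**2))

    def test_flat_zero_trace_rejected(self):
        t = np.linspace(0, 10, 100)
        with pytest.raises(TraceError):
            half_time(KineticTrace(times=t, signal=np.zeros_like(t)))


class TestMaxSlope:
    def test_logistic_slope_quarter_rate(self):
        k, t_inf = max_slope(logistic_trace(rate=0.8))
        assert k == pytest.approx(0.8 / 4, rel=1e-2)
        assert t_inf == pytest.approx(10.0, abs=0.1)

    def test_linear_ramp_constant_slope(self):
        t = np.linspace(0, 10, 200)
        k, _ = max_slope(KineticTrace(times=t, signal=0.3 * t))
        assert k == pytest.approx(0.3, rel=1e-6)

    def test_inflexion_near_half_time_for_symmetric_curve(self):
        tr = logistic_trace()
        th = half_time(tr)
        _, t_inf = max_slope(tr)
        dt = tr.times[1] - tr.times[0]
        assert abs(t_inf - th) <= 2 * dt

    def test_needs_five_points(self):
        with pytest.raises(TraceError):
            max_slope(KineticTrace(times=np.arange(4.0), signal=np.arange(4.0)))


class TestLagTime:
    def test_tangent_intercept_arithmetic(self):
        assert lag_time(10.0, 0.25, 1.0) == pytest.approx(8.0)

    def test_step_like_curve_lag_equals_half_time(self):
        assert lag_time(10.0, 1e9, 1.0) == pytest.approx(10.0, abs=1e-6)

    def test_floored_at_zero_and_rejects_flat_slope(self):
        assert lag_time(1.0, 0.01, 1.0) == 0.0
        with pytest.raises(ValueError):
            lag_time(10.0, 0.0, 1.0)

    def test_matches_tangent_construction_on_logistic(self):
        tr = logistic_trace(rate=0.8)
        th, plateau = half_time(tr, return_plateau=True)
        k, t_inf = max_slope(tr)
        # tangent through (t_inf, plateau/2) hits zero at t_inf - plateau/(2k)
        expected = t_inf - (plateau / 2) / k
        assert lag_time(th, k, plateau) == pytest.approx(expected, rel=1e-2)


class TestFitSigmoid:
    def test_noiseless_parameters_recovered(self):
        tr = logistic_trace(t_half=12.0, rate=0.5, plateau=2.0)
        fit = fit_sigmoid(tr)
        assert fit.t_mid == pytest.approx(12.0, rel=1e-6)
        assert fit.plateau == pytest.approx(2.0, rel=1e-6)
        assert fit.k_max == pytest.approx(2.0 * 0.5 / 4, rel=1e-6)

    def test_constant_trace_rejected(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(TraceError):
            fit_sigmoid(KineticTrace(times=t, signal=np.ones_like(t)))

    def test_midpoint_unbiased_under_noise(self, rng):
        errs = []
        for _ in range(60):
            tr = logistic_trace(n=201)
            noisy = KineticTrace(
                times=tr.times,
                signal=tr.signal * (1 + 0.02 * rng.standard_normal(tr.times.size)),
            )
            errs.append(fit_sigmoid(noisy).t_mid - 10.0)
        errs = np.asarray(errs)
        se = errs.std(ddof=1) / np.sqrt(errs.size)
        assert abs(errs.mean()) < 2 * se + 1e-3


class TestApparentNucleusSize:
    def test_constructed_inverse_power_law(self):
        c0 = np.array([1.0, 2.0, 4.0, 8.0])
        assert apparent_nucleus_size(c0, 5.0 / c0) == pytest.approx((-1.0, 2.0))

    def test_constant_half_times_give_zero(self):
        slope, n_app = apparent_nucleus_size([1, 2, 4], [3.0, 3.0, 3.0])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert n_app == pytest.approx(0.0, abs=1e-12)

    def test_alternative_convention(self):
        c0 = np.array([1.0, 2.0, 4.0])
        _, n_app = apparent_nucleus_size(c0, 5.0 / c0, convention="2s-1")
        assert n_app == pytest.approx(1.0)

    def test_needs_three_positive_points(self):
        with pytest.raises(ValueError):
            apparent_nucleus_size([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            apparent_nucleus_size([1.0, 2.0, -1.0], [1.0, 2.0, 3.0])
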