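"""The nine kinematic features: derivative filters, sub-movements,
speed-curvature gradient, log-decile speeds, SPARC and tracing error."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tracekin.cohort import CohortConfig, GroupProfile, simulate_trial_trajectory
from tracekin.kinematics import (
    FEATURE_NAMES,
    _sparc_single,
    differentiate,
    extract_features,
    min_max_speed,
    sparc,
    speed_modulation,
    submovement_percentage,
    tracing_error,
)
from tracekin.preprocessing import CleanTrajectory, preprocess_trial
from tracekin.shapes import ShapeSpec, generate_pure_frequency_shape


def make_clean(x, y, rate=60.0):
    n = len(x)
    return CleanTrajectory(
        "P", "CTRL", 1, 1, "ellipse", 1,
        t=np.arange(n) / rate, x=np.asarray(x, float), y=np.asarray(y, float),
        theta_traced=np.full(n, np.nan), traces_completed=np.nan, rate_hz=rate,
    )


class TestDifferentiate:
    def test_uniform_linear_motion(self):
        t = np.arange(300) / 60.0
        series = differentiate(make_clean(120.0 * t, np.zeros_like(t)))
        idx = series.interior
        np.testing.assert_allclose(series.v[idx], 120.0, atol=1e-6)
        np.testing.assert_allclose(series.a[idx], 0.0, atol=1e-6)
        np.testing.assert_allclose(series.j[idx], 0.0, atol=1e-5)

    def test_quadratic_component_acceleration(self):
        t = np.arange(300) / 60.0
        series = differentiate(make_clean(t**2, np.zeros_like(t)))
        # tangential acceleration dv/dt = 2 px/s^2 for x = t^2
        np.testing.assert_allclose(series.a[series.interior], 2.0, atol=1e-6)

    def test_against_dense_central_difference_oracle(self):
        """Speed and acceleration match a central difference computed on a
        10x supersampled version of the same smooth trajectory."""
        rate = 60.0
        t = np.arange(0, 8, 1 / rate)
        fx = lambda t: 200 * np.sin(0.7 * t) + 40 * np.sin(1.9 * t) + 300 * t
        fy = lambda t: 150 * np.cos(0.5 * t)
        series = differentiate(make_clean(fx(t), fy(t)))
        td = np.arange(0, 8, 1 / (10 * rate))
        vx_d = np.gradient(fx(td), td)
        vy_d = np.gradient(fy(td), td)
        v_d = np.interp(t, td, np.hypot(vx_d, vy_d))
        a_d = np.interp(t, td, np.gradient(np.hypot(vx_d, vy_d), td))
        idx = series.interior
        assert np.max(np.abs(series.v[idx] - v_d[idx]) / np.abs(v_d[idx])) < 0.01
        scale = np.abs(a_d[idx]).max()
        assert np.max(np.abs(series.a[idx] - a_d[idx])) / scale < 0.01

    def test_window_validation(self):
        t = np.arange(30) / 60.0
        with pytest.raises(ValueError):
            differentiate(make_clean(t, t), window=10)
        with pytest.raises(ValueError):
            differentiate(make_clean(t[:5], t[:5]), window=11)


class TestSubmovements:
    def test_monotone_ramp_is_zero(self):
        t = np.arange(600) / 60.0
        series = differentiate(make_clean(t**2 + 10 * t, np.zeros_like(t)))
        assert submovement_percentage(series) == 0.0

    def test_sinusoidal_profile_matches_analytic_count(self):
        """v = 1 + 0.1 sin(2*pi*f*t) has 2*f*T acceleration zero crossings."""
        f, T, rate = 2.0, 10.0, 60.0
        t = np.arange(0, T, 1 / rate)
        x = t - 0.1 * np.cos(2 * np.pi * f * t) / (2 * np.pi * f)
        series = differentiate(make_clean(x, np.zeros_like(t)))
        pct = submovement_percentage(series)
        n_int = series.interior.stop - series.interior.start
        t_int = t[series.interior]
        expected = 100.0 * 2 * f * (t_int[-1] - t_int[0]) / (n_int - 1)
        assert pct == pytest.approx(expected, rel=0.06)

    def test_iid_acceleration_near_fifty_percent(self):
        rng = np.random.default_rng(7)
        series = differentiate(make_clean(np.zeros(100), np.zeros(100)))
        series.a = rng.standard_normal(100_000)
        series.interior = slice(0, 100_000)
        assert submovement_percentage(series) == pytest.approx(50.0, abs=0.6)

    @settings(max_examples=6, deadline=None, derandomize=True)
    @given(shift=st.floats(0.0, 10.0), scale=st.floats(0.5, 20.0))
    def test_invariance_to_time_shift_and_spatial_scale(self, shift, scale):
        t = np.arange(0, 8, 1 / 60.0)
        x = 100 * np.sin(0.9 * t) + 30 * t
        y = 80 * np.cos(1.3 * t)
        base = submovement_percentage(differentiate(make_clean(x, y)))
        moved = submovement_percentage(
            differentiate(make_clean(scale * x + shift, scale * y))
        )
        assert moved == pytest.approx(base, abs=1e-9)


class TestSpeedModulation:
    def _simulated_series(self, curves, beta, seed=3):
        cfg = CohortConfig(speed_noise_sd=0.0, error_sd_px=0.0, timestamp_jitter_sd=0.0)
        prof = GroupProfile("CTRL", beta, 500.0, 0.0, 0.45)
        curve = curves["ellipse"]
        traj = simulate_trial_trajectory(curve, prof, 8, cfg, np.random.default_rng(seed))
        clean, _ = preprocess_trial(traj, curve)
        return differentiate(clean)

    def test_exact_power_law(self, curves):
        series = self._simulated_series(curves, 1 / 3)
        res = speed_modulation(series)
        assert res.beta == pytest.approx(1 / 3, abs=0.005)
        assert res.r2 > 0.99
        assert res.reliable

    def test_constant_speed_zero_slope(self, curves):
        series = self._simulated_series(curves, 0.0)
        assert speed_modulation(series).beta <= 0.01

    def test_noisy_power_law(self, curves):
        cfg = CohortConfig(speed_noise_sd=0.05, error_sd_px=1.0, seed=11)
        prof = GroupProfile("CTRL", 1 / 3, 500.0, 0.0, 0.45)
        curve = curves["ellipse"]
        traj = simulate_trial_trajectory(curve, prof, 8, cfg, np.random.default_rng(11))
        clean, _ = preprocess_trial(traj, curve)
        res = speed_modulation(differentiate(clean))
        assert res.beta == pytest.approx(1 / 3, rel=0.05)
        assert res.r2 > 0.9

    def test_short_series_flagged(self):
        t = np.arange(40) / 60.0
        series = differentiate(make_clean(np.sin(t) * 50, np.cos(t) * 50))
        assert not speed_modulation(series).reliable


class TestMinMaxSpeed:
    def test_constant_speed(self):
        t = np.arange(300) / 60.0
        series = differentiate(make_clean(77.0 * t, np.zeros_like(t)))
        lo, hi = min_max_speed(series)
        assert lo == pytest.approx(np.log(77.0), abs=1e-6)
        assert hi == pytest.approx(np.log(77.0), abs=1e-6)

    def test_ten_distinct_values_use_single_extreme(self):
        series = differentiate(make_clean(np.zeros(300), np.zeros(300)))
        series.v = np.arange(1.0, 11.0)
        series.interior = slice(0, 10)
        lo, hi = min_max_speed(series)
        assert lo == pytest.approx(np.log(1.0))
        assert hi == pytest.approx(np.log(10.0))

    def test_uniform_speed_distribution_decile_mean(self):
        """Bottom-decile mean of log v for v ~ U[1, 2] approaches the
        integral of log over [1, 1.1] times 10 (numeric oracle)."""
        rng = np.random.default_rng(1)
        series = differentiate(make_clean(np.zeros(300), np.zeros(300)))
        series.v = rng.uniform(1.0, 2.0, 200_000)
        series.interior = slice(0, len(series.v))
        lo, _ = min_max_speed(series)
        grid = np.linspace(1.0, 1.1, 10_001)
        oracle = np.trapezoid(np.log(grid), grid) / 0.1
        assert lo == pytest.approx(oracle, abs=0.002)


class TestSparc:
    def test_gaussian_profile_matches_quadrature_oracle(self):
        """Spectral arc length of a Gaussian speed bump agrees with direct
        quadrature of the continuous spectrum magnitude."""
        rate = 60.0
        t = np.arange(0, 4, 1 / rate)
        v = np.exp(-0.5 * ((t - 2.0) / 0.3) ** 2)
        got = _sparc_single(v, rate, 20.0, 0.05, pad_factor=64)
        # oracle: dense trapezoid over the analytically smooth FFT spectrum
        nfft = 2 ** 18
        mag = np.abs(np.fft.rfft(v, nfft))
        freq = np.fft.rfftfreq(nfft, 1 / rate)
        mag = mag / mag[0]
        sel = freq <= 20.0
        f_b, m_b = freq[sel], mag[sel]
        i_cut = np.nonzero(m_b >= 0.05)[0][-1]
        f_c, m_c = f_b[: i_cut + 1], m_b[: i_cut + 1]
        oracle = -np.sum(np.hypot(np.diff(f_c / f_c[-1]), np.diff(m_c)))
        assert got == pytest.approx(oracle, abs=1e-3)

    def test_time_scale_invariance(self):
        rate = 60.0
        t1 = np.arange(0, 4, 1 / rate)
        t2 = np.arange(0, 8, 1 / rate)
        v1 = np.exp(-0.5 * ((t1 - 2.0) / 0.3) ** 2)
        v2 = np.exp(-0.5 * ((t2 - 4.0) / 0.6) ** 2)
        s1 = _sparc_single(v1, rate, 20.0, 0.05, 4)
        s2 = _sparc_single(v2, rate, 20.0, 0.05, 4)
        assert s1 == pytest.approx(s2, abs=0.02)

    @settings(max_examples=6, deadline=None, derandomize=True)
    @given(gain=st.floats(0.1, 50.0))
    def test_amplitude_invariance(self, gain):
        rate = 60.0
        t = np.arange(0, 4, 1 / rate)
        v = 1.0 + 0.4 * np.sin(2 * np.pi * 1.3 * t) + 0.1 * np.sin(2 * np.pi * 4.1 * t)
        assert _sparc_single(gain * v, rate, 20.0, 0.05, 4) == pytest.approx(
            _sparc_single(v, rate, 20.0, 0.05, 4), abs=1e-12
        )

    def test_whole_trial_vs_per_element(self, curves):
        """Scoring a multi-element trial whole gives a larger-magnitude
        (more negative) value than the per-element mean, motivating the
        per-element definition."""
        curve = curves["rounded_square"]
        cfg = CohortConfig(seed=21)
        prof = GroupProfile("CTRL", 0.33, 500.0, 0.2, 0.45)
        traj = simulate_trial_trajectory(curve, prof, 6, cfg, np.random.default_rng(21))
        clean, _ = preprocess_trial(traj, curve)
        series = differentiate(clean)
        per_element = sparc(series, curve)
        whole = _sparc_single(series.v[series.interior], 60.0, 20.0, 0.05, 4)
        assert per_element.n_elements >= 4
        assert whole <= per_element.sparc
        assert per_element.sparc < 0

    def test_elements_per_cycle_matches_angular_frequency(self, curves):
        """A p/q-frequency shape contributes p sub-elements per trace."""
        curve = curves["rounded_square"]
        cfg = CohortConfig(speed_noise_sd=0.0, error_sd_px=0.0, timestamp_jitter_sd=0.0)
        prof = GroupProfile("CTRL", 0.33, 500.0, 0.0, 0.45)
        traj = simulate_trial_trajectory(curve, prof, 6, cfg, np.random.default_rng(1))
        clean, _ = preprocess_trial(traj, curve)
        series = differentiate(clean)
        res = sparc(series, curve)
        # ~6 traces minus half-pi trim and partial end elements: 4/cycle
        assert 19 <= res.n_elements <= 24


class TestTracingError:
    def test_perfect_trace_zero_error(self, curves):
        curve = curves["ellipse"]
        cfg = CohortConfig(speed_noise_sd=0.0, error_sd_px=0.0, timestamp_jitter_sd=0.0)
        prof = GroupProfile("CTRL", 0.33, 500.0, 0.0, 0.45)
        traj = simulate_trial_trajectory(curve, prof, 3, cfg, np.random.default_rng(0))
        assert tracing_error(traj, curve, slice(None)) < 0.02

    def test_circle_radial_offset(self):
        c = generate_pure_frequency_shape(ShapeSpec("ellipse", 2, 1, 1e-8))
        cx, cy = c.centroid
        r = np.hypot(c.x - cx, c.y - cy).mean()
        phi = np.linspace(0, 2 * np.pi, 500)
        traj = make_clean(cx + (r + 3.0) * np.cos(phi), cy + (r + 3.0) * np.sin(phi))
        assert tracing_error(traj, c, slice(None)) == pytest.approx(3.0, abs=0.02)


class TestDimensionalScaling:
    def test_time_rescaling_of_acceleration_and_jerk(self):
        """Playing the trajectory k times faster scales a by k^2, j by k^3
        (means compared over the same stretch of the underlying path)."""
        k = 2.0
        xf = lambda u: 200 * np.sin(0.5 * u) + 50 * np.sin(1.1 * u) + 300 * u
        yf = lambda u: 150 * np.cos(0.7 * u)
        t_slow = np.arange(0, 24, 1 / 60.0)
        t_fast = np.arange(0, 24 / k, 1 / 60.0)
        slow = differentiate(make_clean(xf(t_slow), yf(t_slow)))
        fast = differentiate(make_clean(xf(k * t_fast), yf(k * t_fast)))
        win_slow = (t_slow >= 1.0) & (t_slow <= 23.0)
        win_fast = (k * t_fast >= 1.0) & (k * t_fast <= 23.0)
        a_ratio = np.abs(fast.a[win_fast]).mean() / np.abs(slow.a[win_slow]).mean()
        j_ratio = np.abs(fast.j[win_fast]).mean() / np.abs(slow.j[win_slow]).mean()
        assert a_ratio == pytest.approx(k**2, rel=0.01)
        assert j_ratio == pytest.approx(k**3, rel=0.01)


class TestExtractFeatures:
    def test_all_fields_finite_on_simulated_trial(self, curves):
        curve = curves["petals"]
        cfg = CohortConfig(seed=13)
        prof = GroupProfile("ASD", 0.4, 500.0, 0.26, 0.44)
        traj = simulate_trial_trajectory(curve, prof, 5, cfg, np.random.default_rng(13))
        clean, qc = preprocess_trial(traj, curve)
        assert qc.kept
        rec = extract_features(clean, curve)
        for name in FEATURE_NAMES:
            assert np.isfinite(getattr(rec, name)), name
        assert rec.min_speed <= rec.max_speed
        assert 0 <= rec.submovement_pct <= 100
        assert rec.sparc < 0

    def test_determinism(self, curves):
        curve = curves["ellipse"]
        cfg = CohortConfig(seed=4)
        prof = GroupProfile("PD", 0.3, 500.0, 0.2, 0.5)
        recs = []
        for _ in range(2):
            traj = simulate_trial_trajectory(curve, prof, 4, cfg, np.random.default_rng(99))
            clean, _ = preprocess_trial(traj, curve)
            recs.append(extract_features(clean, curve))
        for name in FEATURE_NAMES:
            assert getattr(recs[0], name) == getattr(recs[1], name)
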