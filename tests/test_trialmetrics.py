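"""Tests for per-trial outcome measures (scHR slope, windows, oxygen pulse)."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hrsc
from hrsc import synthcardio as sc, trialmetrics as tm
from hrsc.errors import DomainError, ProcessingError
from hrsc.types import BreathSeries


def hr_series(t, hr, onset=180.0):
    t = np.asarray(t, dtype=float)
    hr = np.asarray(hr, dtype=float)
    return BreathSeries(
        t=t, vo2=np.full_like(t, 2000.0), vco2=np.full_like(t, 1900.0),
        hr=hr, po=np.full_like(t, 100.0), meta={"onset": onset},
    )


class TestComputeSchr:
    def test_exact_line_recovered(self):
        t = np.arange(180, 180 + 541, 5.0)
        hr = 120 + 1.5 * (t / 60 - (180 / 60 + 5))  # slope 1.5 bpm/min past min 5
        slope, r2, n = tm.compute_schr(hr_series(t, np.clip(hr, 1, None)))
        assert slope == pytest.approx(1.5, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_hr_gives_zero(self):
        t = np.arange(180, 760, 5.0)
        slope, r2, n = tm.compute_schr(hr_series(t, np.full_like(t, 131.0)))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert r2 == 1.0

    def test_estimate_within_analytic_se(self):
        # OLS slope sampling distribution on 5-s bins over minutes 5-9
        t = np.arange(480, 721, 5.0)  # onset=180, fit window abs [480, 720]
        x = t / 60.0
        sigma = 2.0
        se = sigma / (np.std(x, ddof=0) * np.sqrt(len(x)))
        rng = np.random.default_rng(42)
        inside = 0
        n_sims = 1000
        for _ in range(n_sims):
            hr = 130 + 2.0 * (x - x[0]) + rng.normal(0, sigma, len(x))
            slope, _, _ = tm.compute_schr(hr_series(t, np.clip(hr, 1, None)))
            inside += abs(slope - 2.0) <= 1.96 * se
        # binomial(1000, .95) 3-sigma band
        assert inside / n_sims > 0.93

    def test_slope_equivariance_and_offset_invariance(self):
        t = np.arange(180, 760, 5.0)
        rng = np.random.default_rng(1)
        base = 120 + rng.normal(0, 3, len(t))
        s0, _, _ = tm.compute_schr(hr_series(t, np.clip(base, 1, None)))
        for extra in (0.7, -0.4, 2.5):
            shifted = base + extra * (t - t[0]) / 60.0
            s1, _, _ = tm.compute_schr(hr_series(t, np.clip(shifted, 1, None)))
            assert s1 - s0 == pytest.approx(extra, abs=1e-9)
        # uniform HR offset leaves the slope unchanged
        s2, _, _ = tm.compute_schr(hr_series(t, np.clip(base + 15, 1, None)))
        assert s2 == pytest.approx(s0, abs=1e-12)

    def test_time_origin_invariance(self):
        rng = np.random.default_rng(2)
        t = np.arange(180, 760, 5.0)
        hr = np.clip(130 + 1.2 * t / 60 + rng.normal(0, 2, len(t)), 1, None)
        s0, _, _ = tm.compute_schr(hr_series(t, hr, onset=180.0), onset=180.0)
        s1, _, _ = tm.compute_schr(hr_series(t + 500, hr, onset=680.0), onset=680.0)
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_unbiased_over_simulated_trials(self, subject, heavy_target):
        errs = []
        for seed in range(400):
            series, truth = hrsc.simulate_constant_trial(
                subject, heavy_target, 540, seed=seed
            )
            slope, _, _ = tm.compute_schr(series)
            errs.append(slope - truth.true_schr)
        errs = np.asarray(errs)
        se = errs.std(ddof=1) / np.sqrt(len(errs))
        assert abs(errs.mean()) < 2 * se

    def test_too_few_points_raises(self):
        t = np.array([180.0, 480.0])
        with pytest.raises(ProcessingError):
            tm.compute_schr(hr_series(t, [100.0, 120.0]))


class TestWindowsAndRatios:
    def test_window_mean_of_constant_channel(self):
        t = np.arange(0, 600, 1.0)
        series = hr_series(t, np.full_like(t, 150.0))
        for minute in (5, 6):
            assert tm.window_value(series, "hr", minute) == 150.0
        # vo2 2000, hr 150 -> oxygen pulse 13.33
        assert tm.window_value(series, "vo2", 5) / tm.window_value(series, "hr", 5) == \
            pytest.approx(13.3333, abs=1e-3)

    def test_o2pulse_constant_example(self):
        t = np.arange(0, 600, 1.0)
        series = BreathSeries(
            t=t, vo2=np.full_like(t, 2500.0), vco2=np.full_like(t, 2400.0),
            hr=np.full_like(t, 150.0), po=np.zeros_like(t), meta={"onset": 180.0},
        )
        o2p = tm.window_value(series, "vo2", 5) / tm.window_value(series, "hr", 5)
        assert o2p == pytest.approx(16.67, abs=0.01)

    def test_window_outside_series_raises(self):
        t = np.arange(0, 200, 1.0)
        with pytest.raises(ProcessingError):
            tm.window_value(hr_series(t, np.full_like(t, 100.0)), "hr", 5)

    @given(schr=st.floats(0.1, 5.0), vo2=st.floats(800.0, 4000.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_relative_schr_scaling_identity(self, schr, vo2):
        # equal relative scHR with a VO2 ratio of 1.25 means a 1.25x absolute ratio
        rel = tm.relative_schr(schr, vo2)
        assert tm.relative_schr(1.25 * schr, 1.25 * vo2) == pytest.approx(rel, rel=1e-9)

    def test_relative_schr_values_and_errors(self):
        assert tm.relative_schr(2.0, 2000.0) == pytest.approx(1.0)
        assert tm.relative_schr(0.0, 1234.0) == 0.0
        with pytest.raises(DomainError):
            tm.relative_schr(1.0, 0.0)

    @pytest.mark.parametrize(
        "vo2_5,rcp,expected", [(2000, 2000, 100.0), (1608, 2000, 80.4), (500, 2000, 25.0)]
    )
    def test_pct_rcp_values(self, vo2_5, rcp, expected):
        assert tm.pct_rcp(vo2_5, rcp) == pytest.approx(expected)
        with pytest.raises(DomainError):
            tm.pct_rcp(vo2_5, 0.0)


class TestComputeMetrics:
    def test_full_metrics_on_noiseless_trial(self, subject, heavy_target, noiseless_trial):
        from hrsc import breathproc
        series, truth = noiseless_trial
        m = tm.compute_metrics(breathproc.clean_trial(series), subject)
        assert m.schr == pytest.approx(truth.true_schr, abs=1e-6)
        assert m.vo2_5min == pytest.approx(heavy_target, rel=5e-3)
        assert m.pct_rcp == pytest.approx(100 * heavy_target / subject.vo2_rcp, rel=5e-3)
        assert m.o2pulse_5 > 0 and m.o2pulse_9 is not None
        assert m.schr_rel == pytest.approx(m.schr / (m.vo2_5min / 1000), rel=1e-9)

    def test_short_trial_has_no_ninth_minute_pulse(self, subject, heavy_target, zero_noise):
        series, _ = hrsc.simulate_constant_trial(
            subject, heavy_target, 420, seed=3, noise=zero_noise
        )
        from hrsc import breathproc
        m = tm.compute_metrics(breathproc.clean_trial(series), subject, fit_start=200.0)
        assert m.o2pulse_9 is None
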