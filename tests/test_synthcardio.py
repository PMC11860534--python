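"""Tests for the synthetic population and trial generator."""
import dataclasses
from collections import Counter

import numpy as np
import pytest

import hrsc
from hrsc import breathproc, synthcardio as sc, trialmetrics as tm
from hrsc.errors import ConfigurationError, DomainError, InputError


def _age_group(age):
    return "young" if age < 36 else ("middle" if age <= 55 else "elderly")


class TestGeneratePopulation:
    def test_strata_counts_match_cohort_plan(self):
        pop = hrsc.generate_population(65, seed=1)
        groups = Counter(_age_group(p.age) for p in pop)
        assert groups == {"young": 23, "middle": 22, "elderly": 20}
        females = Counter(
            _age_group(p.age) for p in pop if p.sex == "female"
        )
        assert females == {"young": 12, "middle": 12, "elderly": 10}

    def test_same_seed_reproduces_population(self):
        a = hrsc.generate_population(1, seed=9)
        b = hrsc.generate_population(1, seed=9)
        assert a[0] == b[0]
        c = hrsc.generate_population(1, seed=10)
        assert c[0] != a[0]

    def test_profiles_satisfy_physiological_invariants(self):
        for p in hrsc.generate_population(200, seed=3):
            assert 0 < p.get_frac < p.rcp_frac < 1
            assert p.vo2_rest < p.vo2_get
            assert abs(p.vo2max_abs - p.vo2max_rel * p.body_mass) < 1e-6
            assert p.hr_rest < p.hrmax
            assert p.age >= 18

    def test_sample_moments_converge_to_configured_means(self):
        # law of large numbers at n = 10^4 against the generating values
        pop = hrsc.generate_population(10_000, seed=11)
        females = np.array([p.vo2max_rel for p in pop if p.sex == "female"])
        males = np.array([p.vo2max_rel for p in pop if p.sex == "male"])
        for vals, mu, sd in ((females, 41.4, 7.1), (males, 51.0, 11.0)):
            se = sd / np.sqrt(len(vals))
            assert abs(vals.mean() - mu) < 2 * se

    def test_invalid_strata_rejected(self):
        with pytest.raises(ConfigurationError):
            hrsc.generate_population(10, seed=0, strata={("young", "male"): -1.0})
        with pytest.raises(ConfigurationError):
            hrsc.generate_population(10, seed=0, strata={("ancient", "male"): 1.0})
        with pytest.raises(InputError):
            hrsc.generate_population(0, seed=0)


class TestSimulateConstantTrial:
    def test_truth_slope_follows_equation_at_100_pct_rcp(self, male_35, zero_noise):
        # at %RCP = 100, age 35, male: -0.0514 + 2.40 - 0.602 = 1.7466
        _, truth = hrsc.simulate_constant_trial(
            male_35, male_35.vo2_rcp, 540, seed=1, noise=zero_noise
        )
        assert truth.true_schr == pytest.approx(1.7466, abs=1e-12)
        assert truth.pct_rcp == pytest.approx(100.0, abs=1e-9)

    def test_sample_timing_and_span(self, subject, heavy_target):
        series, _ = hrsc.simulate_constant_trial(subject, heavy_target, 540, seed=2)
        assert series.t[-1] <= 540 + 180
        assert len(series) >= (540 + 180) / 4
        assert np.all(np.diff(series.t) > 0)

    def test_same_seed_bit_identical(self, subject, heavy_target):
        a, _ = hrsc.simulate_constant_trial(subject, heavy_target, 540, seed=5)
        b, _ = hrsc.simulate_constant_trial(subject, heavy_target, 540, seed=5)
        assert np.array_equal(a.t, b.t) and np.array_equal(a.hr, b.hr)

    def test_noiseless_closure(self, noiseless_trial, heavy_target):
        # slope and 5th-minute VO2 recover the generating truth
        series, truth = noiseless_trial
        slope, _, _ = tm.compute_schr(series)
        assert slope == pytest.approx(truth.true_schr, abs=1e-6)
        clean = breathproc.clean_trial(series)
        vo2_5 = tm.window_value(clean, "vo2", 5)
        assert abs(vo2_5 - heavy_target) / heavy_target < 0.005

    def test_hr_capped_at_hrmax(self, subject):
        series, _ = hrsc.simulate_constant_trial(
            subject, subject.vo2max_abs, 540, seed=3
        )
        assert np.all(series.hr <= subject.hrmax + 1e-9)

    @pytest.mark.parametrize(
        "target_factor,duration", [(1.05, 540), (0.5, 300)]
    )
    def test_invalid_inputs_rejected(self, subject, target_factor, duration):
        with pytest.raises(DomainError):
            hrsc.simulate_constant_trial(
                subject, target_factor * subject.vo2max_abs, duration, seed=0
            )

    def test_truncation_flag_floors_negative_slopes(self, zero_noise):
        # an elderly female at a low intensity predicts a negative slope
        pop = hrsc.generate_population(40, seed=8)
        p = next(q for q in pop if q.sex == "female" and q.age > 56)
        tgt = hrsc.target_vo2(
            "moderate", 0.33, p.vo2_rest, p.vo2_get, p.vo2_rcp, p.vo2max_abs
        )
        _, free = hrsc.simulate_constant_trial(p, tgt, 540, seed=1, noise=zero_noise)
        _, floored = hrsc.simulate_constant_trial(
            p, tgt, 540, seed=1, noise=zero_noise, truncate_negative_schr=True
        )
        assert free.true_schr < 0
        assert floored.true_schr == 0.0


class TestInjectAberrant:
    def test_rate_zero_is_identity(self, noiseless_trial):
        series, _ = noiseless_trial
        out, idx = hrsc.inject_aberrant(series, rate=0.0, magnitude=5, seed=1)
        assert len(idx) == 0
        assert np.array_equal(out.hr, series.hr)

    def test_same_seed_same_indices(self, noiseless_trial):
        series, _ = noiseless_trial
        _, a = hrsc.inject_aberrant(series, rate=0.05, magnitude=5, seed=4)
        _, b = hrsc.inject_aberrant(series, rate=0.05, magnitude=5, seed=4)
        assert np.array_equal(a, b)

    def test_displacements_at_least_magnitude_times_local_sd(self, subject, heavy_target):
        series, _ = hrsc.simulate_constant_trial(subject, heavy_target, 540, seed=6)
        out, idx = hrsc.inject_aberrant(series, rate=0.05, magnitude=5, seed=2)
        assert len(idx) > 0
        onset = series.meta["onset"]
        # all injected points sit outside the protected transition
        assert not np.any((series.t[idx] > onset) & (series.t[idx] < onset + 180))
        # each displaced HR moved by at least 5 x the windowed residual SD
        for mask in ((series.t <= onset), (series.t >= onset + 180)):
            if mask.sum() < 4:
                continue
            _, sd = breathproc.window_fit(series.t[mask], series.hr[mask])
            here = idx[mask[idx]]
            moved = np.abs(out.hr[here] - series.hr[here])
            assert np.all(moved >= 5 * sd - 1e-9)

    def test_expected_outlier_count(self, subject, heavy_target):
        counts = []
        for seed in range(10):
            series, _ = hrsc.simulate_constant_trial(
                subject, heavy_target, 540, seed=seed
            )
            _, idx = hrsc.inject_aberrant(series, rate=0.05, magnitude=5, seed=seed)
            counts.append(len(idx))
        onset = 180.0
        series, _ = hrsc.simulate_constant_trial(subject, heavy_target, 540, seed=0)
        n_eligible = np.sum((series.t <= onset) | (series.t >= onset + 180))
        assert np.mean(counts) == pytest.approx(0.05 * n_eligible, rel=0.5)

    def test_invalid_rate_or_magnitude(self, noiseless_trial):
        series, _ = noiseless_trial
        with pytest.raises(InputError):
            hrsc.inject_aberrant(series, rate=0.5, magnitude=5, seed=0)
        with pytest.raises(InputError):
            hrsc.inject_aberrant(series, rate=0.1, magnitude=2, seed=0)


class TestSimulateRamp:
    def test_noiseless_ramp_reaches_configured_maxima(self, subject, zero_noise):
        series, info = hrsc.simulate_ramp(subject, seed=1, noise=zero_noise)
        assert series.vo2.max() == pytest.approx(subject.vo2max_abs, rel=1e-9)
        assert series.hr.max() == pytest.approx(subject.hrmax, rel=1e-9)
        assert series.t[-1] == pytest.approx(info["exhaustion_t"])
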