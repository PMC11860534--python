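"""Synthetic cardiopulmonary data with known ground truth.

Emulates a two-step exercise study on a cycle ergometer:

* an age/sex-stratified population whose maximal parameters and
  ventilatory thresholds follow configurable normal distributions
  (defaults mimic a healthy, active adult cohort);
* constant-work-rate trials — 3 min of freewheeling baseline, an
  instantaneous step in power, mono-exponential primary VO2/HR
  kinetics, and from minute 5 a linear HR slow component whose slope is
  drawn from the scHR prediction equation plus a Gaussian residual;
* ramp tests with a pure-delay mean response time, for calibrating the
  VO2/power relationship;
* injectable aberrant breaths, for exercising the outlier screen.

All randomness flows through a single integer seed per call; identical
inputs give bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import breathproc
from .errors import ConfigurationError, DomainError, InputError
from .schrmodel import SchrModel, PUBLISHED, predict_schr
from .types import BreathSeries, SubjectProfile, TrialTruth

__all__ = [
    "AGE_GROUPS",
    "PopulationConfig",
    "NoiseConfig",
    "KineticsConfig",
    "RampProtocol",
    "default_strata",
    "generate_population",
    "simulate_constant_trial",
    "simulate_ramp",
    "inject_aberrant",
]

#: Age-group boundaries (years): young < 36, middle 36–55, elderly > 55.
AGE_GROUPS = {
    "young": (18.0, 35.0),
    "middle": (36.0, 55.0),
    "elderly": (56.0, 75.0),
}


def default_strata() -> dict:
    """Default stratification plan: proportions per (age group, sex).

    Mirrors a 65-subject cohort of 23 young (12 female), 22 middle-aged
    (12 female) and 20 elderly (10 female).
    """
    counts = {
        ("young", "male"): 11,
        ("young", "female"): 12,
        ("middle", "male"): 10,
        ("middle", "female"): 12,
        ("elderly", "male"): 10,
        ("elderly", "female"): 10,
    }
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass(frozen=True)
class PopulationConfig:
    """Generating distributions for subject parameters.

    Each entry is (mean, SD) of a truncated normal.  VO2max is relative
    to body mass (mL·min⁻¹·kg⁻¹); GET and RCP are fractions of VO2max.
    HRmax is centred on the age-predicted 208 − 0.7·age so that maximal
    HR and age are realistically cross-correlated.
    """

    vo2max_rel_male: tuple = (51.0, 11.0)
    vo2max_rel_female: tuple = (41.4, 7.1)
    # symmetric +-3.5 SD truncation: guards against absurd draws without
    # shifting the stratum mean
    vo2max_rel_trunc_sd: float = 3.5
    get_frac: tuple = (0.621, 0.071)
    get_frac_bounds: tuple = (0.40, 0.80)
    rcp_frac: tuple = (0.845, 0.060)
    rcp_frac_bounds: tuple = (0.65, 0.97)
    min_get_rcp_gap: float = 0.05
    hrmax_sd: float = 8.0
    hr_rest: tuple = (65.0, 8.0)
    hr_rest_bounds: tuple = (45.0, 90.0)
    bmi_male: tuple = (24.0, 2.0)
    bmi_female: tuple = (22.0, 2.0)
    bmi_bounds: tuple = (17.0, 32.0)
    height_male: tuple = (178.0, 7.0)
    height_female: tuple = (165.0, 6.0)
    height_bounds: tuple = (145.0, 205.0)
    vo2_rest_per_kg: tuple = (3.5, 0.3)  # mL/min/kg
    vo2_rest_per_kg_bounds: tuple = (2.5, 4.5)
    vo2_po_slope: tuple = (10.2, 0.8)  # mL/min/W
    vo2_po_slope_bounds: tuple = (8.0, 13.0)
    mrt: tuple = (40.0, 10.0)  # s
    mrt_bounds: tuple = (15.0, 75.0)


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement and biological noise magnitudes.

    ``hr_sd`` is additive per-breath HR noise (bpm); ``vo2_frac_sd`` and
    ``vco2_frac_sd`` scale with the signal; ``hr_day_sd`` is a per-trial
    HR offset emulating day-to-day variability; ``sigma_resid`` is the
    SD of the Gaussian residual added to the equation-predicted slow
    component slope (bpm·min⁻¹).
    """

    hr_sd: float = 2.0
    vo2_frac_sd: float = 0.03
    vco2_frac_sd: float = 0.03
    hr_day_sd: float = 1.8
    sigma_resid: float = 0.61

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class KineticsConfig:
    """Primary-kinetics time constants and breath-timing model.

    ``tau_vo2``/``tau_hr`` are per-domain mono-exponential time
    constants (s).  The primary phase is normalised to complete exactly
    ``primary_complete`` s after exercise onset (about 4–5 time
    constants for the defaults), and the slow component ramps linearly
    from ``sc_onset`` s after onset.  ``hr_fraction_gain`` maps the
    target VO2 fraction of reserve into the HR reserve; the sub-unity
    default leaves the physiological headroom observed between 5th-min
    HR and true maximal HR in severe-domain exercise.
    """

    tau_vo2: dict = field(
        default_factory=lambda: {"moderate": 30.0, "heavy": 35.0, "severe": 40.0}
    )
    tau_hr: dict = field(
        default_factory=lambda: {"moderate": 35.0, "heavy": 40.0, "severe": 45.0}
    )
    breath_interval: tuple = (2.0, 4.0)  # s, uniform
    sc_onset: float = 300.0  # s after exercise onset
    primary_complete: float = 180.0  # s after exercise onset
    hr_fraction_gain: float = 0.85


@dataclass(frozen=True)
class RampProtocol:
    """Ramp-test protocol settings."""

    baseline_po: float = 50.0  # W
    baseline_dur: float = 360.0  # s
    ramp_rate: float = 25.0  # W/min
    hold: float = 30.0  # s held at VO2max before exhaustion


def _apportion(n: int, strata: dict) -> dict:
    """Largest-remainder apportionment of n subjects across strata."""
    total = sum(strata.values())
    if any(v < 0 for v in strata.values()) or total <= 0:
        raise ConfigurationError("strata proportions must be non-negative and sum > 0")
    props = {k: v / total for k, v in strata.items()}
    quotas = {k: n * p for k, p in props.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    remainders = sorted(quotas, key=lambda k: (quotas[k] - counts[k]), reverse=True)
    for k in remainders[:short]:
        counts[k] += 1
    return counts


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def generate_population(
    n: int,
    seed: int,
    strata: Optional[dict] = None,
    config: Optional[PopulationConfig] = None,
) -> list:
    """Draw ``n`` subjects stratified by age group and sex.

    Stratum counts follow largest-remainder apportionment of the
    requested proportions; all physiological fields come from the
    truncated normals in ``config``.  The same seed reproduces the same
    population exactly.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    strata = default_strata() if strata is None else strata
    for key in strata:
        group, sex = key
        if group not in AGE_GROUPS or sex not in ("male", "female"):
            raise ConfigurationError(f"unknown stratum {key!r}")
    cfg = config or PopulationConfig()
    counts = _apportion(n, strata)
    rng = np.random.default_rng(seed)
    profiles = []
    idx = 0
    for (group, sex) in sorted(counts):
        lo_age, hi_age = AGE_GROUPS[group]
        for _ in range(counts[(group, sex)]):
            idx += 1
            age = float(rng.uniform(lo_age, hi_age))
            rel_mu, rel_sd = cfg.vo2max_rel_male if sex == "male" else cfg.vo2max_rel_female
            half = cfg.vo2max_rel_trunc_sd * rel_sd
            vo2max_rel = _trunc_normal(rng, rel_mu, rel_sd, rel_mu - half, rel_mu + half)
            bmi_mu, bmi_sd = cfg.bmi_male if sex == "male" else cfg.bmi_female
            bmi = _trunc_normal(rng, bmi_mu, bmi_sd, *cfg.bmi_bounds)
            h_mu, h_sd = cfg.height_male if sex == "male" else cfg.height_female
            height = _trunc_normal(rng, h_mu, h_sd, *cfg.height_bounds)
            mass = bmi * (height / 100.0) ** 2
            get_frac = _trunc_normal(rng, *cfg.get_frac, *cfg.get_frac_bounds)
            for _ in range(1000):
                rcp_frac = _trunc_normal(rng, *cfg.rcp_frac, *cfg.rcp_frac_bounds)
                if rcp_frac >= get_frac + cfg.min_get_rcp_gap:
                    break
            else:  # pragma: no cover - defensive
                rcp_frac = min(get_frac + cfg.min_get_rcp_gap, 0.97)
            hr_rest = _trunc_normal(rng, *cfg.hr_rest, *cfg.hr_rest_bounds)
            hrmax = _trunc_normal(
                rng, 208.0 - 0.7 * age, cfg.hrmax_sd, hr_rest + 60.0, 220.0
            )
            rest_per_kg = _trunc_normal(rng, *cfg.vo2_rest_per_kg, *cfg.vo2_rest_per_kg_bounds)
            slope = _trunc_normal(rng, *cfg.vo2_po_slope, *cfg.vo2_po_slope_bounds)
            mrt = _trunc_normal(rng, *cfg.mrt, *cfg.mrt_bounds)
            profiles.append(
                SubjectProfile(
                    subject_id=f"S{idx:03d}",
                    age=age,
                    sex=sex,
                    body_mass=mass,
                    height=height,
                    vo2_rest=rest_per_kg * mass,
                    vo2max_abs=vo2max_rel * mass,
                    vo2max_rel=vo2max_rel,
                    hrmax=hrmax,
                    hr_rest=hr_rest,
                    get_frac=get_frac,
                    rcp_frac=rcp_frac,
                    vo2_po_slope=slope,
                    mrt=mrt,
                )
            )
    return profiles


def classify_domain(subject: SubjectProfile, target_vo2: float) -> str:
    """Intensity domain of a target VO2: moderate < GET < heavy < RCP < severe."""
    if target_vo2 < subject.vo2_get:
        return "moderate"
    if target_vo2 < subject.vo2_rcp:
        return "heavy"
    return "severe"


def _breath_times(rng: np.random.Generator, total: float, interval: tuple, knots) -> np.ndarray:
    lo, hi = interval
    n_max = int(total / lo) + 3
    gaps = rng.uniform(lo, hi, size=n_max)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    t = t[t <= total]
    # make the model's knots exactly representable under linear interpolation
    t = np.unique(np.concatenate([t, [k for k in knots if 0.0 < k <= total]]))
    return t


def _phase(delta: np.ndarray, tau: float, complete: float) -> np.ndarray:
    """Normalised mono-exponential rise, complete at ``complete`` s."""
    norm = 1.0 - np.exp(-complete / tau)
    rise = (1.0 - np.exp(-np.clip(delta, 0.0, None) / tau)) / norm
    return np.where(delta <= 0.0, 0.0, np.where(delta >= complete, 1.0, rise))


def simulate_constant_trial(
    subject: SubjectProfile,
    target_vo2: float,
    duration: float,
    seed: int,
    noise: Optional[NoiseConfig] = None,
    kinetics: Optional[KineticsConfig] = None,
    model: SchrModel = PUBLISHED,
    truncate_negative_schr: bool = False,
    baseline_dur: float = 180.0,
    trial_label: str = "",
) -> tuple:
    """Simulate one constant-work-rate trial.

    ``duration`` is exercise time after onset (s, >= 360); the series
    additionally carries a 180-s freewheeling baseline before the step.
    The HR slow component slope is the equation prediction at the
    trial's nominal %RCP plus Normal(0, ``noise.sigma_resid``); with
    ``truncate_negative_schr`` the realized slope is floored at zero.
    Returns ``(BreathSeries, TrialTruth)``.
    """
    noise = NoiseConfig() if noise is None else noise
    kin = KineticsConfig() if kinetics is None else kinetics
    if not subject.vo2_rest < target_vo2:
        raise DomainError("target_vo2 must exceed resting VO2")
    if target_vo2 > subject.vo2max_abs:
        raise DomainError("target_vo2 above VO2max")
    if duration < 360.0:
        raise DomainError("duration must be >= 360 s")

    rng = np.random.default_rng(seed)
    domain = classify_domain(subject, target_vo2)
    tau_vo2 = kin.tau_vo2[domain]
    tau_hr = kin.tau_hr[domain]
    pct_rcp = 100.0 * target_vo2 / subject.vo2_rcp

    s_pred = predict_schr(pct_rcp, subject.age, subject.sex, model=model)
    s_real = s_pred + (rng.normal(0.0, noise.sigma_resid) if noise.sigma_resid > 0 else 0.0)
    if truncate_negative_schr:
        s_real = max(0.0, s_real)
    day_offset = rng.normal(0.0, noise.hr_day_sd) if noise.hr_day_sd > 0 else 0.0

    total = baseline_dur + duration
    knots = (baseline_dur, baseline_dur + kin.primary_complete, baseline_dur + kin.sc_onset)
    t = _breath_times(rng, total, kin.breath_interval, knots)
    delta = t - baseline_dur

    amp_vo2 = target_vo2 - subject.vo2_rest
    vo2_true = subject.vo2_rest + amp_vo2 * _phase(delta, tau_vo2, kin.primary_complete)
    frac = amp_vo2 / (subject.vo2max_abs - subject.vo2_rest)
    amp_hr = kin.hr_fraction_gain * subject.hr_reserve * frac
    slow = s_real * np.clip(delta - kin.sc_onset, 0.0, None) / 60.0
    hr_true = subject.hr_rest + amp_hr * _phase(delta, tau_hr, kin.primary_complete) + slow
    rer = np.clip(0.80 + 0.35 * vo2_true / subject.vo2max_abs, None, 1.20)
    vco2_true = rer * vo2_true
    po = np.where(delta > 0, (target_vo2 - subject.vo2_rest) / subject.vo2_po_slope, 0.0)

    n_s = len(t)
    vo2 = vo2_true + (rng.normal(0.0, 1.0, n_s) * (noise.vo2_frac_sd * vo2_true)
                      if noise.vo2_frac_sd > 0 else 0.0)
    vco2 = vco2_true + (rng.normal(0.0, 1.0, n_s) * (noise.vco2_frac_sd * vco2_true)
                        if noise.vco2_frac_sd > 0 else 0.0)
    hr = hr_true + day_offset + (rng.normal(0.0, noise.hr_sd, n_s) if noise.hr_sd > 0 else 0.0)
    hr = np.clip(hr, 30.0, subject.hrmax)
    vo2 = np.clip(vo2, 1.0, None)
    vco2 = np.clip(vco2, 1.0, None)

    series = BreathSeries(
        t=t, vo2=vo2, vco2=vco2, hr=hr, po=po,
        meta={
            "subject_id": subject.subject_id,
            "trial_label": trial_label,
            "domain": domain,
            "onset": baseline_dur,
        },
    )
    truth = TrialTruth(
        true_schr=float(s_real),
        true_vo2_ss=float(target_vo2),
        tau_hr=tau_hr,
        tau_vo2=tau_vo2,
        hr_amplitude=float(amp_hr),
        outlier_indices=[],
        pct_rcp=float(pct_rcp),
    )
    return series, truth


def simulate_ramp(
    subject: SubjectProfile,
    seed: int,
    noise: Optional[NoiseConfig] = None,
    protocol: Optional[RampProtocol] = None,
) -> tuple:
    """Simulate a ramp test: loaded baseline bout, then a linear ramp.

    VO2 responds to the ramp as a pure time delay of ``subject.mrt``
    seconds and plateaus at VO2max, which the subject holds for
    ``protocol.hold`` seconds before exhaustion.  Returns
    ``(BreathSeries, info)`` where ``info`` holds the exhaustion time
    and protocol timing.
    """
    noise = NoiseConfig() if noise is None else noise
    prot = RampProtocol() if protocol is None else protocol
    rng = np.random.default_rng(seed)

    vo2_b = subject.vo2_rest + subject.vo2_po_slope * prot.baseline_po
    if vo2_b >= subject.vo2max_abs:
        raise DomainError("baseline power too high for this subject")
    k = subject.vo2_po_slope * prot.ramp_rate / 60.0  # mL/min per s of ramp
    t_r = prot.baseline_dur
    t_max = t_r + subject.mrt + (subject.vo2max_abs - vo2_b) / k
    exhaustion_t = t_max + prot.hold

    knots = (t_r, t_r + subject.mrt, t_max, exhaustion_t)
    t = _breath_times(rng, exhaustion_t, (2.0, 4.0), knots)
    ramp_elapsed = np.clip(t - t_r - subject.mrt, 0.0, None)
    vo2_true = np.minimum(vo2_b + k * ramp_elapsed, subject.vo2max_abs)
    hr_true = subject.hr_rest + subject.hr_reserve * (
        (vo2_true - subject.vo2_rest) / (subject.vo2max_abs - subject.vo2_rest)
    )
    rer = 0.78 + 0.40 * (vo2_true / subject.vo2max_abs) ** 2
    vco2_true = rer * vo2_true
    po = np.where(t < t_r, prot.baseline_po, prot.baseline_po + prot.ramp_rate / 60.0 * (t - t_r))

    n_s = len(t)
    vo2 = vo2_true + (rng.normal(0.0, 1.0, n_s) * (noise.vo2_frac_sd * vo2_true)
                      if noise.vo2_frac_sd > 0 else 0.0)
    vco2 = vco2_true + (rng.normal(0.0, 1.0, n_s) * (noise.vco2_frac_sd * vco2_true)
                        if noise.vco2_frac_sd > 0 else 0.0)
    hr = hr_true + (rng.normal(0.0, noise.hr_sd, n_s) if noise.hr_sd > 0 else 0.0)
    hr = np.clip(hr, 30.0, subject.hrmax)
    vo2 = np.clip(vo2, 1.0, None)
    vco2 = np.clip(vco2, 1.0, None)

    series = BreathSeries(
        t=t, vo2=vo2, vco2=vco2, hr=hr, po=po,
        meta={"subject_id": subject.subject_id, "trial_label": "ramp", "domain": "ramp",
              "onset": t_r},
    )
    info = {
        "exhaustion_t": float(exhaustion_t),
        "t_ramp_start": float(t_r),
        "t_plateau": float(t_max),
        "baseline_ss_vo2": float(vo2_b),
        "protocol": prot,
    }
    return series, info


_INJECT_CHANNELS = ("vo2", "vco2", "hr")


def inject_aberrant(
    series: BreathSeries,
    rate: float,
    magnitude: float,
    seed: int,
    onset: Optional[float] = None,
    channels: Sequence[str] = _INJECT_CHANNELS,
) -> tuple:
    """Displace random breaths to emulate aberrant data points.

    Candidate breaths are restricted to the regions the outlier screen
    examines (baseline and steady state); the 0–180 s post-onset
    transition is never touched.  Each selected breath is displaced by
    ±``magnitude`` × local scale, where the local scale is the residual
    SD of the window's linear fit, floored at the channel's nominal
    measurement noise (2 bpm for HR, 3% of the window mean for gas
    channels) so that the displacement is meaningful even on noiseless
    signals.  Returns ``(new_series, indices)``.
    """
    if not (0.0 <= rate < 0.2):
        raise InputError("rate must be in [0, 0.2)")
    if magnitude <= 3.0:
        raise InputError("magnitude must exceed 3 local SDs")
    if onset is None:
        onset = float(series.meta.get("onset", 180.0))
    out = series.copy()
    if rate == 0.0:
        return out, np.array([], dtype=int)

    rng = np.random.default_rng(seed)
    t = series.t
    base_mask = (t >= onset - 180.0) & (t <= onset)
    steady_mask = t >= onset + 180.0
    eligible = np.flatnonzero(base_mask | steady_mask)
    picked = eligible[rng.random(len(eligible)) < rate]
    for ch in channels:
        y = out.channel(ch)
        scale = np.zeros_like(y)
        for mask in (base_mask, steady_mask):
            if mask.sum() < 4:
                continue
            _, sd = breathproc.window_fit(t[mask], y[mask])
            floor = 2.0 if ch == "hr" else 0.03 * float(np.nanmean(y[mask]))
            scale[mask] = max(sd, floor)
        signs = np.where(rng.random(len(picked)) < 0.5, -1.0, 1.0)
        y[picked] += signs * magnitude * scale[picked]
    # keep channels physiologically valid after displacement
    out.hr = np.clip(out.hr, 1.0, None)
    out.vo2 = np.clip(out.vo2, 1.0, None)
    out.vco2 = np.clip(out.vco2, 1.0, None)
    return out, np.sort(picked)
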