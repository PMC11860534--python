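"""Core value types shared across the pipeline.

Units follow exercise-physiology conventions throughout: oxygen uptake
(VO2) and CO2 output (VCO2) in mL·min⁻¹, heart rate (HR) in beats·min⁻¹
(bpm), power output in W, time in seconds, the HR slow component (scHR)
in bpm·min⁻¹.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DomainError, InputError

__all__ = [
    "SubjectProfile",
    "BreathSeries",
    "CleanSeries",
    "TrialTruth",
    "RampResult",
    "TrialSpec",
    "TrialMetrics",
    "AgreementReport",
    "SEX_LABELS",
    "sex_code",
]

SEX_LABELS = ("male", "female")


def sex_code(sex: str | int | float) -> float:
    """Map a sex label to the regression coding (male = 0, female = 1)."""
    if isinstance(sex, str):
        try:
            return float(SEX_LABELS.index(sex.lower()))
        except ValueError:
            raise InputError(f"unknown sex label {sex!r}; expected one of {SEX_LABELS}")
    v = float(sex)
    if v not in (0.0, 1.0):
        raise InputError(f"sex code must be 0 (male) or 1 (female), got {sex!r}")
    return v


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics and ramp-derived anchors for one subject.

    ``get_frac`` and ``rcp_frac`` are the gas exchange threshold and
    respiratory compensation point expressed as fractions of VO2max;
    ``vo2_po_slope`` is the steady-state VO2/power gain (mL·min⁻¹·W⁻¹)
    and ``mrt`` the mean response time of VO2 to a ramp (s).
    """

    subject_id: str
    age: float  # years
    sex: str  # "male" | "female"
    body_mass: float  # kg
    height: float  # cm
    vo2_rest: float  # mL/min
    vo2max_abs: float  # mL/min
    vo2max_rel: float  # mL/min/kg
    hrmax: float  # bpm
    hr_rest: float  # bpm
    get_frac: float  # fraction of VO2max
    rcp_frac: float  # fraction of VO2max
    vo2_po_slope: float  # mL/min/W
    mrt: float  # s

    def __post_init__(self) -> None:
        if self.sex not in SEX_LABELS:
            raise InputError(f"sex must be one of {SEX_LABELS}, got {self.sex!r}")
        if not (0.0 < self.get_frac < self.rcp_frac < 1.0):
            raise DomainError(
                f"need 0 < get_frac < rcp_frac < 1, got {self.get_frac}, {self.rcp_frac}"
            )
        if not self.vo2_rest < self.get_frac * self.vo2max_abs:
            raise DomainError("vo2_rest must lie below VO2 at GET")
        if not abs(self.vo2max_abs - self.vo2max_rel * self.body_mass) <= 0.02 * self.vo2max_abs:
            raise DomainError("vo2max_abs inconsistent with vo2max_rel * body_mass")
        if not self.hr_rest < self.hrmax:
            raise DomainError("hr_rest must be below hrmax")
        if self.age < 18:
            raise DomainError("age must be >= 18 years")

    @property
    def vo2_get(self) -> float:
        """VO2 at the gas exchange threshold (mL/min)."""
        return self.get_frac * self.vo2max_abs

    @property
    def vo2_rcp(self) -> float:
        """VO2 at the respiratory compensation point (mL/min)."""
        return self.rcp_frac * self.vo2max_abs

    @property
    def hr_reserve(self) -> float:
        return self.hrmax - self.hr_rest


_CHANNELS = ("vo2", "vco2", "hr", "po")


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class BreathSeries:
    """Time-stamped breath-by-breath samples for one trial.

    Sampling may be irregular. Individual channel values may be NaN
    after per-channel outlier removal; timestamps are never NaN.
    """

    t: np.ndarray  # s, strictly increasing
    vo2: np.ndarray  # mL/min
    vco2: np.ndarray  # mL/min
    hr: np.ndarray  # bpm
    po: np.ndarray  # W
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t)
        for name in _CHANNELS:
            arr = _as_float_array(getattr(self, name))
            if arr.shape != self.t.shape:
                raise InputError(f"channel {name!r} length differs from t")
            setattr(self, name, arr)
        if self.t.ndim != 1 or len(self.t) == 0:
            raise InputError("t must be a non-empty 1-D array")
        if np.any(np.isnan(self.t)) or np.any(np.diff(self.t) <= 0):
            raise InputError("t must be strictly increasing and finite")
        for name in ("vo2", "hr"):
            vals = getattr(self, name)
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise DomainError(f"channel {name!r} must be positive at every sample")

    def __len__(self) -> int:
        return len(self.t)

    def channel(self, name: str) -> np.ndarray:
        if name not in _CHANNELS:
            raise InputError(f"unknown channel {name!r}; expected one of {_CHANNELS}")
        return getattr(self, name)

    def copy(self) -> "BreathSeries":
        return BreathSeries(
            t=self.t.copy(),
            vo2=self.vo2.copy(),
            vco2=self.vco2.copy(),
            hr=self.hr.copy(),
            po=self.po.copy(),
            meta=dict(self.meta),
        )


@dataclass
class CleanSeries:
    """Channels resampled onto a regular 5-s grid (bin centres).

    ``removed_count`` records, per channel, how many raw breaths the
    outlier screen deleted before interpolation.
    """

    t: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    hr: np.ndarray
    po: np.ndarray
    removed_count: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t)
        for name in _CHANNELS:
            arr = _as_float_array(getattr(self, name))
            if arr.shape != self.t.shape:
                raise InputError(f"channel {name!r} length differs from t")
            setattr(self, name, arr)
        if len(self.t) >= 2 and not np.allclose(np.diff(self.t), 5.0):
            raise InputError("CleanSeries grid spacing must be exactly 5 s")

    def __len__(self) -> int:
        return len(self.t)

    def channel(self, name: str) -> np.ndarray:
        if name not in _CHANNELS:
            raise InputError(f"unknown channel {name!r}; expected one of {_CHANNELS}")
        return getattr(self, name)


@dataclass
class TrialTruth:
    """Ground truth stored by the simulator for recovery tests."""

    true_schr: float  # bpm/min (realized slope actually used in the HR signal)
    true_vo2_ss: float  # mL/min
    tau_hr: float  # s
    tau_vo2: float  # s
    hr_amplitude: float  # bpm
    outlier_indices: list = field(default_factory=list)
    pct_rcp: Optional[float] = None  # nominal intensity used to draw the slope


@dataclass
class RampResult:
    """Maximal parameters and VO2/power calibration from a ramp test.

    ``baseline_po`` is the constant power of the pre-ramp bout at which
    ``baseline_ss_vo2`` was measured; it anchors the power inversion.
    """

    vo2max_abs: float  # mL/min
    rer_max: float
    hrmax: float  # bpm
    ramp_slope: float  # mL/min/W
    mrt: float  # s
    baseline_ss_vo2: float  # mL/min
    baseline_po: float = 0.0  # W

    def __post_init__(self) -> None:
        if self.rer_max <= 0:
            raise DomainError("rer_max must be positive")
        if self.vo2max_abs <= self.baseline_ss_vo2:
            raise DomainError("vo2max_abs must exceed baseline steady-state VO2")
        if self.mrt < 0:
            raise DomainError("mrt must be non-negative")


@dataclass(frozen=True)
class TrialSpec:
    """A prescribed constant-work trial: domain, anchor fraction, targets."""

    domain: str  # "moderate" | "heavy" | "severe"
    fraction: float
    target_vo2: float  # mL/min
    target_po: float  # W
    pct_rcp_nominal: float  # %


@dataclass
class TrialMetrics:
    """Per-trial outcome measures."""

    schr: float  # bpm/min
    schr_rel: float  # bpm/min per L/min of 5th-minute VO2
    o2pulse_5: float  # mL/beat
    o2pulse_9: Optional[float]  # mL/beat, None for trials shorter than 9 min
    hr_5min: float  # bpm
    vo2_5min: float  # mL/min
    pct_rcp: float  # %
    fit_r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InputError("n_points must be >= 2")
        if not self.pct_rcp > 0:
            raise DomainError("pct_rcp must be positive")
        for v in (self.o2pulse_5, self.o2pulse_9):
            if v is not None and v <= 0:
                raise DomainError("oxygen pulse must be positive when present")


@dataclass
class AgreementReport:
    """Bland–Altman summary of measured vs. estimated end-exercise HR."""

    bias: float  # bpm, mean(measured - estimated)
    sd_diff: float  # bpm
    loa_low: float  # bpm
    loa_high: float  # bpm
    z_score: float  # bias / sd_diff
    pearson_r2: float
    n_pairs: int


def _replace(obj, **kw):
    return replace(obj, **kw)
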