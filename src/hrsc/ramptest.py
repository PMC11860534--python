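"""Ramp-test analysis and intensity-domain exercise prescription.

From a ramp incremental test this module derives the maximal
parameters (VO2max, RERmax, HRmax), the VO2/power ramp slope corrected
for the mean response time (MRT), and the domain-anchored target VO2
and power output for constant-work trials.

Intensity anchoring: a moderate target lies a fraction of the way from
resting VO2 to the gas exchange threshold (GET); heavy between GET and
the respiratory compensation point (RCP); severe between RCP and
VO2max.  GET and RCP are inputs here — for synthetic subjects they are
known; their visual determination from gas-exchange plots is a
measurement procedure outside this package.
"""
from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .errors import ConfigurationError, DomainError, ProcessingError
from .types import BreathSeries, CleanSeries, RampResult, SubjectProfile, TrialSpec

__all__ = [
    "max_params",
    "compute_mrt",
    "fit_ramp_line",
    "analyze_ramp",
    "target_vo2",
    "vo2_to_po",
    "prescribe_trial",
    "STEP1_ANCHORS",
    "STEP2_ANCHORS",
]

#: Six development-step anchors: two per domain at 33% and 66%.
STEP1_ANCHORS = (
    ("moderate", 0.33), ("moderate", 0.66),
    ("heavy", 0.33), ("heavy", 0.66),
    ("severe", 0.33), ("severe", 0.66),
)
#: Three validation-step anchors at 50% of each domain.
STEP2_ANCHORS = (("moderate", 0.50), ("heavy", 0.50), ("severe", 0.50))

Series = Union[BreathSeries, CleanSeries]


def max_params(ramp: Series, exhaustion_t: float) -> dict:
    """Maximal parameters from the end of a ramp test.

    VO2max and RERmax are means over the final 30 s before exhaustion;
    HRmax is the highest HR of the whole test.
    """
    t = ramp.t
    if t[0] > exhaustion_t - 30.0 or t[-1] < exhaustion_t - 1e-9:
        raise ProcessingError("series does not cover the final 30 s before exhaustion")
    win = (t >= exhaustion_t - 30.0) & (t <= exhaustion_t)
    if win.sum() < 2:
        raise ProcessingError("final 30-s window holds fewer than 2 samples")
    vo2 = ramp.channel("vo2")[win]
    vco2 = ramp.channel("vco2")[win]
    return {
        "vo2max_abs": float(np.nanmean(vo2)),
        "rer_max": float(np.nanmean(vco2 / vo2)),
        "hrmax": float(np.nanmax(ramp.channel("hr"))),
    }


def compute_mrt(
    baseline_ss_vo2: float,
    baseline_po: float,
    ramp_fit: tuple,
    ramp_rate: float,
    po_start: float,
    ramp_duration: Optional[float] = None,
) -> float:
    """Mean response time (s) of VO2 during a ramp.

    ``ramp_fit`` is ``(a, b)`` of the line VO2 = a + b·t with t in
    seconds from ramp onset.  The MRT is the time shift between the
    moment the ramp's power passes ``baseline_po`` and the moment the
    fitted VO2 line passes the measured steady state at that power —
    the leftward shift that aligns the ramp VO2/power relation with
    steady-state exercise.  Clamped at zero.
    """
    a, b = ramp_fit
    if b <= 0:
        raise ProcessingError("ramp VO2 fit must have positive slope")
    if ramp_rate <= 0:
        raise ConfigurationError("ramp_rate must be positive")
    t_vo2 = (baseline_ss_vo2 - a) / b
    if ramp_duration is not None and t_vo2 > ramp_duration:
        raise ProcessingError("fitted line never reaches the baseline VO2 within the ramp")
    t_po = (baseline_po - po_start) * 60.0 / ramp_rate
    return max(0.0, float(t_vo2 - t_po))


def fit_ramp_line(series: Series, t_start: float, t_end: float) -> tuple:
    """OLS line VO2 = a + b·t over [t_start, t_end] (absolute seconds)."""
    t = series.t
    mask = (t >= t_start) & (t <= t_end)
    vo2 = series.channel("vo2")[mask]
    valid = ~np.isnan(vo2)
    if valid.sum() < 4:
        raise ProcessingError("fewer than 4 valid points in the ramp fit window")
    b, a = np.polyfit(t[mask][valid], vo2[valid], 1)
    return float(a), float(b)


def analyze_ramp(series: Series, protocol, exhaustion_t: float) -> RampResult:
    """Derive a full :class:`RampResult` from a ramp series.

    ``protocol`` supplies the baseline power/duration and ramp rate
    (see ``synthcardio.RampProtocol``).  The baseline steady-state VO2
    is the mean over the final 60 s of the baseline bout; the ramp line
    is fitted between 90 s after ramp onset (past the MRT transient)
    and 10 s before the VO2 plateau.
    """
    t_r = protocol.baseline_dur
    t = series.t
    base_win = (t >= t_r - 60.0) & (t <= t_r)
    if base_win.sum() < 4:
        raise ProcessingError("baseline steady-state window too short")
    baseline_ss = float(np.nanmean(series.channel("vo2")[base_win]))
    mp = max_params(series, exhaustion_t)
    plateau_start = exhaustion_t - getattr(protocol, "hold", 30.0)
    a_abs, b = fit_ramp_line(series, t_r + 90.0, plateau_start - 10.0)
    a = a_abs + b * t_r  # re-reference intercept to the ramp clock
    mrt = compute_mrt(
        baseline_ss, protocol.baseline_po, (a, b), protocol.ramp_rate,
        po_start=protocol.baseline_po, ramp_duration=exhaustion_t - t_r,
    )
    ramp_slope = b * 60.0 / protocol.ramp_rate
    return RampResult(
        vo2max_abs=mp["vo2max_abs"],
        rer_max=mp["rer_max"],
        hrmax=mp["hrmax"],
        ramp_slope=ramp_slope,
        mrt=mrt,
        baseline_ss_vo2=baseline_ss,
        baseline_po=protocol.baseline_po,
    )


def target_vo2(
    domain: str,
    fraction: float,
    vo2_rest: float,
    vo2_get: float,
    vo2_rcp: float,
    vo2max_abs: float,
) -> float:
    """Domain-anchored target VO2 (mL/min).

    moderate: rest + f·(GET − rest); heavy: GET + f·(RCP − GET);
    severe: RCP + f·(VO2max − RCP).
    """
    if not (vo2_rest < vo2_get < vo2_rcp < vo2max_abs):
        raise DomainError("need vo2_rest < GET < RCP < VO2max")
    if not (0.0 < fraction < 1.0):
        raise DomainError("fraction must lie in (0, 1)")
    if domain == "moderate":
        return vo2_rest + fraction * (vo2_get - vo2_rest)
    if domain == "heavy":
        return vo2_get + fraction * (vo2_rcp - vo2_get)
    if domain == "severe":
        return vo2_rcp + fraction * (vo2max_abs - vo2_rcp)
    raise DomainError(f"unknown domain {domain!r}")


def vo2_to_po(
    target: float,
    ramp: RampResult,
    vo2_get: float,
    sc_gain: float = 0.0,
) -> float:
    """Power output (W) eliciting a target VO2.

    Inverts the MRT-corrected linear VO2/power relation.  Above GET an
    optional slow-component correction steepens the effective gain by
    ``sc_gain`` (mL·min⁻¹·W⁻¹) over the above-GET portion, lowering the
    prescribed power relative to the naive inversion.
    """
    if ramp.ramp_slope <= 0 or ramp.ramp_slope + sc_gain <= 0:
        raise ConfigurationError("VO2/power slope must be positive")
    if target <= ramp.baseline_ss_vo2:
        raise DomainError("target must exceed the baseline steady-state VO2")
    if target <= vo2_get:
        return ramp.baseline_po + (target - ramp.baseline_ss_vo2) / ramp.ramp_slope
    po_get = ramp.baseline_po + (vo2_get - ramp.baseline_ss_vo2) / ramp.ramp_slope
    return po_get + (target - vo2_get) / (ramp.ramp_slope + sc_gain)


def prescribe_trial(
    subject: SubjectProfile,
    domain: str,
    fraction: float,
    ramp: Optional[RampResult] = None,
    sc_gain: float = 0.0,
) -> TrialSpec:
    """Build a :class:`TrialSpec` for a subject from domain and fraction.

    Without a measured ``ramp``, the subject's known parameters stand
    in for the ramp calibration (slope = ``vo2_po_slope``, baseline =
    rest at 0 W).
    """
    tv = target_vo2(
        domain, fraction, subject.vo2_rest, subject.vo2_get,
        subject.vo2_rcp, subject.vo2max_abs,
    )
    if ramp is None:
        ramp = RampResult(
            vo2max_abs=subject.vo2max_abs,
            rer_max=1.1,
            hrmax=subject.hrmax,
            ramp_slope=subject.vo2_po_slope,
            mrt=subject.mrt,
            baseline_ss_vo2=subject.vo2_rest,
            baseline_po=0.0,
        )
    po = vo2_to_po(tv, ramp, subject.vo2_get, sc_gain=sc_gain)
    return TrialSpec(
        domain=domain,
        fraction=fraction,
        target_vo2=tv,
        target_po=po,
        pct_rcp_nominal=100.0 * tv / subject.vo2_rcp,
    )
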