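"""Per-trial outcome measures for constant-work-rate exercise.

The heart-rate slow component (scHR) is the OLS slope of HR against
time-in-minutes from the fifth minute of exercise to the end of the
trial.  "At the fifth minute" values (HR, VO2, oxygen pulse) are means
over the 30-s window ending at that minute, mirroring the 30-s
convention used for maximal parameters.
"""
from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .errors import DomainError, ProcessingError
from .types import BreathSeries, CleanSeries, SubjectProfile, TrialMetrics

__all__ = [
    "compute_schr",
    "relative_schr",
    "window_value",
    "pct_rcp",
    "compute_metrics",
]

Series = Union[BreathSeries, CleanSeries]


def compute_schr(
    series: Series,
    onset: Optional[float] = None,
    fit_start: float = 300.0,
    fit_end: Optional[float] = None,
) -> tuple:
    """scHR as the OLS slope of HR vs time (bpm·min⁻¹).

    The fit runs over t in [onset + fit_start, onset + fit_end]
    (inclusive; ``fit_end`` defaults to the end of the series), with
    time expressed in minutes.  Returns ``(slope, r2, n_points)``.
    """
    if onset is None:
        onset = float(getattr(series, "meta", {}).get("onset", 180.0))
    t = series.t
    hi = t[-1] if fit_end is None else onset + fit_end
    mask = (t >= onset + fit_start - 1e-9) & (t <= hi + 1e-9)
    hr = series.channel("hr")[mask]
    tt = t[mask]
    valid = ~np.isnan(hr)
    if valid.sum() < 2:
        raise ProcessingError("fewer than 2 points in the scHR fit window")
    x = tt[valid] / 60.0
    y = hr[valid]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0.0:
        r2 = 1.0 if ss_res <= 1e-12 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(r2), int(valid.sum())


def relative_schr(schr: float, vo2_5min: float) -> float:
    """scHR normalised to the fifth-minute VO2 (bpm·min⁻¹ per L·min⁻¹)."""
    if vo2_5min <= 0:
        raise DomainError("vo2_5min must be positive")
    return schr / (vo2_5min / 1000.0)


def window_value(
    series: Series,
    channel: str,
    minute: float,
    onset: Optional[float] = None,
    width: float = 30.0,
    clamp_end: bool = False,
) -> float:
    """Mean of a channel over the window ending at a given minute.

    The window is [onset + 60·minute − width, onset + 60·minute].  With
    ``clamp_end`` the right edge is clamped to the last sample, so a
    window that loses its tail to 5-s binning is still usable.
    """
    if onset is None:
        onset = float(getattr(series, "meta", {}).get("onset", 180.0))
    t = series.t
    hi = onset + 60.0 * minute
    lo = hi - width
    if clamp_end:
        hi = min(hi, float(t[-1]))
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
        raise ProcessingError(
            f"window [{lo:.0f}, {hi:.0f}] s outside series span [{t[0]:.0f}, {t[-1]:.0f}]"
        )
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    vals = series.channel(channel)[mask]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ProcessingError("no valid samples in the window")
    return float(np.mean(vals))


def pct_rcp(vo2_5min: float, vo2_rcp: float) -> float:
    """Fifth-minute VO2 as a percentage of VO2 at RCP."""
    if vo2_rcp <= 0:
        raise DomainError("vo2_rcp must be positive")
    return 100.0 * vo2_5min / vo2_rcp


def compute_metrics(
    series: Series,
    subject: SubjectProfile,
    onset: Optional[float] = None,
    fit_start: float = 300.0,
    fit_end: Optional[float] = None,
    window_width: float = 30.0,
) -> TrialMetrics:
    """All per-trial measures: scHR, oxygen pulse, 5th-minute values, %RCP.

    Oxygen pulse is the ratio of window-mean VO2 to window-mean HR over
    the same 30-s window (not the mean of per-breath ratios).  The
    9th-minute oxygen pulse is ``None`` for trials shorter than 9 min.
    """
    if onset is None:
        onset = float(getattr(series, "meta", {}).get("onset", 180.0))
    schr, r2, n = compute_schr(series, onset=onset, fit_start=fit_start, fit_end=fit_end)
    vo2_5 = window_value(series, "vo2", 5, onset=onset, width=window_width)
    hr_5 = window_value(series, "hr", 5, onset=onset, width=window_width)
    o2p_5 = vo2_5 / hr_5
    if series.t[-1] >= onset + 540.0 - window_width / 2:
        vo2_9 = window_value(series, "vo2", 9, onset=onset, width=window_width,
                             clamp_end=True)
        hr_9 = window_value(series, "hr", 9, onset=onset, width=window_width,
                            clamp_end=True)
        o2p_9 = vo2_9 / hr_9
    else:
        o2p_9 = None
    return TrialMetrics(
        schr=schr,
        schr_rel=relative_schr(schr, vo2_5),
        o2pulse_5=o2p_5,
        o2pulse_9=o2p_9,
        hr_5min=hr_5,
        vo2_5min=vo2_5,
        pct_rcp=pct_rcp(vo2_5, subject.vo2_rcp),
        fit_r2=r2,
        n_points=n,
    )
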