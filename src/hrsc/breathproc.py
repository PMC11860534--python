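"""Breath-by-breath signal cleaning.

Three stages, applied per channel:

1. :func:`remove_aberrant` — ordinary least-squares lines are fitted to
   the pre-onset baseline (onset − 180 s … onset) and the steady-state
   portion (onset + 180 s … end); breaths whose residual exceeds
   ``sd_mult`` residual SDs are deleted.  Nothing inside the first
   180 s of the transition is ever removed.
2. :func:`interpolate_1s` — linear interpolation onto a 1-s grid.
3. :func:`bin_5s` — aggregation into non-overlapping 5-s bins
   timestamped at the bin centre.

:func:`clean_trial` chains the three.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .errors import InputError, ProcessingError
from .types import BreathSeries, CleanSeries

__all__ = [
    "window_fit",
    "remove_aberrant",
    "interpolate_1s",
    "bin_5s",
    "clean_trial",
]

#: channels subject to outlier screening (power output is a controlled input)
CLEAN_CHANNELS = ("vo2", "vco2", "hr")

# residual SDs below this relative level are treated as exactly zero
# (an analytically flat window otherwise turns round-off into "outliers")
_SD_EPS = 1e-9


def window_fit(t: np.ndarray, y: np.ndarray):
    """OLS line through (t, y); returns (predicted values, residual SD).

    The residual SD uses the n − 2 denominator (residual standard
    error).  NaNs in ``y`` are ignored for fitting but predictions are
    returned for every ``t``.
    """
    valid = ~np.isnan(y)
    n = int(valid.sum())
    if n < 4:
        raise ProcessingError(f"need >= 4 points in a fitting window, got {n}")
    b, a = np.polyfit(t[valid], y[valid], 1)
    pred = a + b * t
    resid = y[valid] - pred[valid]
    sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return pred, sd


def remove_aberrant(
    series: BreathSeries,
    onset: Optional[float] = None,
    sd_mult: float = 3.0,
    channels: Sequence[str] = CLEAN_CHANNELS,
) -> tuple:
    """Delete aberrant breaths via windowed linear fits.

    Per channel, two lines are fitted in a single pass (no refit after
    removal): baseline window [onset − 180, onset] and steady-state
    window [onset + 180, end].  A breath is deleted (set to NaN in that
    channel only) when |residual| > ``sd_mult`` × the window's residual
    SD.  Breaths with t in (onset, onset + 180) are never deleted.
    Returns ``(cleaned_series, removed)`` with ``removed`` a dict
    mapping channel → sorted indices.
    """
    if onset is None:
        onset = float(series.meta.get("onset", 180.0))
    t = series.t
    if t[0] > onset - 180.0 + 1e-9 or t[-1] < onset + 240.0 - 1e-9:
        raise ProcessingError("series must span [onset-180, onset+240] s")
    base_mask = (t >= onset - 180.0) & (t <= onset)
    steady_mask = t >= onset + 180.0
    out = series.copy()
    removed: dict = {}
    for ch in channels:
        y = out.channel(ch)
        idx: list = []
        for name, mask in (("baseline", base_mask), ("steady-state", steady_mask)):
            if int((~np.isnan(y[mask])).sum()) < 4:
                raise ProcessingError(
                    f"fewer than 4 valid points in the {name} window of channel {ch!r}"
                )
            pred, sd = window_fit(t[mask], y[mask])
            scale = max(1.0, float(np.nanmean(np.abs(y[mask]))))
            if sd <= _SD_EPS * scale:
                continue
            resid = y[mask] - pred
            bad = np.flatnonzero(mask)[np.abs(resid) > sd_mult * sd]
            idx.extend(int(i) for i in bad)
        y[idx] = np.nan
        removed[ch] = np.array(sorted(idx), dtype=int)
    return out, removed


def interpolate_1s(series: BreathSeries) -> BreathSeries:
    """Linearly interpolate every channel onto a 1-s integer grid.

    The grid spans every integer second in [ceil(t_first),
    floor(t_last)]; source samples falling on integer seconds are
    preserved exactly.  NaNs (removed breaths) are bridged linearly
    from their valid neighbours.
    """
    t = series.t
    grid = np.arange(math.ceil(t[0]), math.floor(t[-1]) + 1, dtype=float)
    if len(grid) == 0:
        raise ProcessingError("series too short to interpolate")
    channels = {}
    for ch in ("vo2", "vco2", "hr", "po"):
        y = series.channel(ch)
        valid = ~np.isnan(y)
        if int(valid.sum()) < 2:
            raise ProcessingError(f"channel {ch!r} has fewer than 2 valid samples")
        channels[ch] = np.interp(grid, t[valid], y[valid])
    return BreathSeries(t=grid, meta=dict(series.meta), **channels)


def bin_5s(series: BreathSeries, statistic: str = "mean") -> CleanSeries:
    """Aggregate a 1-s regular series into 5-s bins.

    Bins are the non-overlapping windows [5k, 5k + 5) aligned to
    absolute multiples of 5 s; each bin's value is the mean (or median)
    of its five samples and its timestamp is the window centre
    (5k + 2 s).  Leading samples before the first aligned window and a
    trailing partial window are dropped.
    """
    if statistic not in ("mean", "median"):
        raise InputError("statistic must be 'mean' or 'median'")
    t = series.t
    if len(t) < 2 or not np.allclose(np.diff(t), 1.0):
        raise ProcessingError("bin_5s requires a 1-s regular grid")
    start = int(math.ceil(t[0] / 5.0) * 5)
    first = int(start - t[0])
    n_bins = (len(t) - first) // 5
    if n_bins < 1:
        raise ProcessingError("series too short for a single 5-s bin")
    agg = np.mean if statistic == "mean" else np.median
    channels = {}
    for ch in ("vo2", "vco2", "hr", "po"):
        y = series.channel(ch)[first : first + 5 * n_bins].reshape(n_bins, 5)
        channels[ch] = agg(y, axis=1)
    t_bins = start + 5.0 * np.arange(n_bins) + 2.0
    return CleanSeries(
        t=t_bins,
        removed_count={ch: 0 for ch in CLEAN_CHANNELS},
        provenance=str(series.meta.get("trial_label", "")),
        **channels,
    )


def clean_trial(
    series: BreathSeries,
    onset: Optional[float] = None,
    sd_mult: float = 3.0,
    statistic: str = "mean",
) -> CleanSeries:
    """Full cleaning chain: outlier removal → 1-s interpolation → 5-s bins."""
    cleaned, removed = remove_aberrant(series, onset=onset, sd_mult=sd_mult)
    binned = bin_5s(interpolate_1s(cleaned), statistic=statistic)
    binned.removed_count = {ch: int(len(ix)) for ch, ix in removed.items()}
    return binned
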