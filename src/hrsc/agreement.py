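"""Agreement statistics for validating dynamic HR-target projection.

The projected end-exercise heart rate is

    HR@end = HR@5min + scHR · (t_end − 5)

with t_end in minutes from exercise onset.  Measured vs. projected HR
pairs are compared by Bland–Altman analysis (bias, limits of agreement
at ±1.96 SD of the differences) and the squared Pearson correlation;
freewheeling HR repeatability is summarised by the within-subject
coefficient of variation.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InputError
from .types import AgreementReport

__all__ = ["project_hr", "bland_altman", "within_subject_cv", "bland_altman_plot"]

LOA_MULTIPLIER = 1.96


def project_hr(hr_5min: float, schr: float, t_end: float) -> float:
    """Project HR to ``t_end`` minutes from onset using the scHR slope."""
    if np.any(np.asarray(t_end) < 5.0):
        raise DomainError("t_end must be >= 5 minutes")
    return hr_5min + schr * (np.asarray(t_end, dtype=float) - 5.0)


def bland_altman(measured: Sequence[float], estimated: Sequence[float]) -> AgreementReport:
    """Bland–Altman agreement between measured and estimated HR.

    Differences are oriented measured − estimated, so a positive bias
    means the projection under-predicts.  ``sd_diff`` uses the n − 1
    sample SD; the z-score is bias / sd_diff.
    """
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape or m.ndim != 1:
        raise InputError("measured and estimated must be 1-D and of equal length")
    n = len(m)
    if n < 3:
        raise InputError("need at least 3 pairs")
    d = m - e
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.allclose(m, m[0]) or np.allclose(e, e[0]):
        r2 = 1.0 if np.allclose(d, d[0]) else 0.0
    elif np.allclose(d, d[0]):
        r2 = 1.0  # measured = estimated + constant: exactly collinear
    else:
        r, _ = stats.pearsonr(m, e)
        r2 = float(r**2)
    z = bias / sd if sd > 0 else 0.0
    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        z_score=float(z),
        pearson_r2=r2,
        n_pairs=n,
    )


def within_subject_cv(replicates: Iterable[Sequence[float]]) -> tuple:
    """Within-subject coefficient of variation across replicate trials.

    For each subject, CV = 100·SD/mean over that subject's replicate HR
    values; returns ``(mean, sd)`` of the CVs across subjects (%).
    """
    cvs = []
    for reps in replicates:
        x = np.asarray(reps, dtype=float)
        if len(x) < 2:
            raise InputError("each subject needs at least 2 replicates")
        mu = float(np.mean(x))
        if mu == 0:
            raise DomainError("zero-mean replicate set")
        cvs.append(100.0 * float(np.std(x, ddof=1)) / mu)
    if not cvs:
        raise InputError("no subjects given")
    arr = np.asarray(cvs)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def bland_altman_plot(measured, estimated, path: Optional[str] = None):
    """Standard Bland–Altman scatter (difference vs. pair mean).

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = bland_altman(measured, estimated)
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((m + e) / 2.0, m - e, s=18, color="k", alpha=0.7)
    for yv, style in ((rep.bias, "-"), (rep.loa_low, "--"), (rep.loa_high, "--")):
        ax.axhline(yv, linestyle=style, color="gray")
    ax.set_xlabel("mean of measured and estimated HR (bpm)")
    ax.set_ylabel("measured − estimated HR (bpm)")
    ax.set_title(f"bias {rep.bias:.2f} bpm, LoA [{rep.loa_low:.2f}, {rep.loa_high:.2f}]")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
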