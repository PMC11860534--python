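"""Prediction model for the heart-rate slow component (scHR).

The central object is a linear model

    scHR (bpm·min⁻¹) = b0 + b1·%RCP + b2·age + b3·sex

where %RCP is exercise intensity as a percentage of the VO2 at the
respiratory compensation point, age is in years, and sex is coded
male = 0 / female = 1.  ``PUBLISHED`` holds the reference coefficients
for healthy adults; :func:`forward_select` refits the model from data
by forward stepwise OLS with collinearity screening, and
:func:`recover_parameters` runs the whole simulate → clean → estimate →
refit chain as a parameter-recovery harness.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, FittingError, InputError
from .types import sex_code

__all__ = [
    "SchrModel",
    "PUBLISHED",
    "predict_schr",
    "forward_select",
    "recover_parameters",
    "RecoveryResult",
]


@dataclass(frozen=True)
class SchrModel:
    """Coefficients and fit diagnostics of an scHR linear model.

    ``coefficients`` maps predictor names to slopes; canonical names are
    ``pct_rcp``, ``age`` and ``sex``.  ``see`` is the standard error of
    estimate (residual SD on n − p − 1 degrees of freedom).
    """

    intercept: float
    coefficients: dict = field(default_factory=dict)
    r2: Optional[float] = None
    see: Optional[float] = None
    n_obs: Optional[int] = None
    selected_predictors: tuple = ()

    def __post_init__(self) -> None:
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise InputError("r2 must lie in [0, 1]")
        if self.see is not None and self.see < 0:
            raise InputError("see must be non-negative")

    @property
    def beta_pctrcp(self) -> float:
        return self.coefficients.get("pct_rcp", 0.0)

    @property
    def beta_age(self) -> float:
        return self.coefficients.get("age", 0.0)

    @property
    def beta_sex(self) -> float:
        return self.coefficients.get("sex", 0.0)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "r2": self.r2,
            "see": self.see,
            "n_obs": self.n_obs,
            "selected_predictors": list(self.selected_predictors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SchrModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            r2=None if d.get("r2") is None else float(d["r2"]),
            see=None if d.get("see") is None else float(d["see"]),
            n_obs=None if d.get("n_obs") is None else int(d["n_obs"]),
            selected_predictors=tuple(d.get("selected_predictors", ())),
        )


#: Reference coefficients for healthy adults (male = 0, female = 1).
PUBLISHED = SchrModel(
    intercept=-0.0514,
    coefficients={"pct_rcp": 0.0240, "age": -0.0172, "sex": -0.347},
    r2=0.53,
    see=0.61,
    selected_predictors=("pct_rcp", "age", "sex"),
)


def predict_schr(pct_rcp, age, sex, model: SchrModel = PUBLISHED):
    """Predicted scHR (bpm·min⁻¹) at an intensity, age and sex.

    Parameters
    ----------
    pct_rcp : float or array
        Exercise intensity as % of VO2 at RCP (>= 0).
    age : float or array
        Age in years (>= 0).
    sex : str, int or array
        "male"/"female" or the 0/1 coding.
    model : SchrModel
        Defaults to the reference coefficients.

    The value may be negative; truncation (e.g. at zero for a subject
    whose HR is not expected to drift down) is the caller's policy.
    """
    pct = np.asarray(pct_rcp, dtype=float)
    a = np.asarray(age, dtype=float)
    if np.any(pct < 0):
        raise DomainError("pct_rcp must be non-negative")
    if np.any(a < 0):
        raise DomainError("age must be non-negative")
    if isinstance(sex, (str, int, float)):
        s = sex_code(sex)
    else:
        s = np.asarray([sex_code(v) for v in sex], dtype=float)
    out = (
        model.intercept
        + model.beta_pctrcp * pct
        + model.beta_age * a
        + model.beta_sex * s
    )
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def _screen(data: pd.DataFrame, included: list, r_cut: float, vif_cut: float) -> list:
    """Return later-entering predictors violating the collinearity rules.

    A pairwise |Pearson r| above ``r_cut`` or a VIF above ``vif_cut``
    discards the predictor that entered the model later.
    """
    drop: list = []
    for i, late in enumerate(included):
        for early in included[:i]:
            r = np.corrcoef(data[late], data[early])[0, 1]
            if abs(r) > r_cut and late not in drop:
                drop.append(late)
    kept = [c for c in included if c not in drop]
    # VIF pass on what survives the pairwise screen, latest entrant first
    changed = True
    while changed and len(kept) >= 2:
        changed = False
        X = sm.add_constant(data[kept].to_numpy(dtype=float))
        for j in range(len(kept) - 1, 0, -1):  # never drop the first entrant
            others = [k for k in range(1, len(kept) + 1) if k != j + 1]
            xj = X[:, j + 1]
            fit = sm.OLS(xj, X[:, [0] + [o for o in others]]).fit()
            vif = 1.0 / max(1.0 - fit.rsquared, 1e-12)
            if vif > vif_cut:
                drop.append(kept[j])
                kept = kept[:j] + kept[j + 1 :]
                changed = True
                break
    return drop


def forward_select(
    data: pd.DataFrame,
    response: str = "schr",
    candidates: Optional[Sequence[str]] = None,
    alpha_in: float = 0.05,
    r_cut: float = 0.70,
    vif_cut: float = 5.0,
) -> SchrModel:
    """Forward stepwise OLS with correlation/VIF screening.

    At each step the candidate with the smallest partial-F p-value below
    ``alpha_in`` enters.  After every entry, pairwise correlations and
    variance inflation factors among the included predictors are
    checked; a violator is discarded from the model *and* from further
    candidacy, with ties resolved against the later entrant.  The final
    model is an ordinary least-squares fit on the surviving set.
    """
    if candidates is None:
        candidates = [c for c in data.columns if c != response]
    candidates = list(candidates)
    if response not in data.columns:
        raise InputError(f"response column {response!r} missing")
    n = len(data)
    if n < 10 * max(len(candidates), 1):
        # the paper-style rule of thumb: >= 10 observations per candidate
        if n < 10:
            raise InputError("need at least 10 observations")
    y = data[response].to_numpy(dtype=float)
    var_y = float(np.var(y))

    included: list = []
    banned: set = set()
    while True:
        remaining = [c for c in candidates if c not in included and c not in banned]
        if not remaining:
            break
        # degenerate-residual guard: a numerically perfect fit admits no
        # further predictors (their partial F on ~zero residuals is noise)
        if included:
            X0 = sm.add_constant(data[included].to_numpy(dtype=float))
            fit0 = sm.OLS(y, X0).fit()
            if fit0.ssr <= 1e-10 * max(var_y, 1.0) * n:
                break
        best, best_p = None, np.inf
        for c in remaining:
            X = sm.add_constant(data[included + [c]].to_numpy(dtype=float))
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            fit = sm.OLS(y, X).fit()
            p = fit.pvalues[-1]
            if p < best_p:
                best, best_p = c, p
        if best is None or best_p >= alpha_in:
            break
        included.append(best)
        for d in _screen(data, included, r_cut, vif_cut):
            included.remove(d)
            banned.add(d)

    X = sm.add_constant(data[included].to_numpy(dtype=float)) if included else np.ones((n, 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FittingError(f"rank-deficient design over columns {included}")
    fit = sm.OLS(y, X).fit()
    coefs = {name: float(b) for name, b in zip(included, fit.params[1:])}
    see = float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0
    model = SchrModel(
        intercept=float(fit.params[0]),
        coefficients=coefs,
        r2=float(min(max(fit.rsquared, 0.0), 1.0)) if included else 0.0,
        see=see,
        n_obs=n,
        selected_predictors=tuple(included),
    )
    # invariant: no two retained predictors may be collinear beyond r_cut
    for i, a_ in enumerate(included):
        for b_ in included[:i]:
            assert abs(np.corrcoef(data[a_], data[b_])[0, 1]) <= r_cut
    return model


@dataclass
class RecoveryResult:
    """Fitted model plus the generating truth it should recover."""

    model: SchrModel
    truth: SchrModel
    conf_int: dict  # predictor -> (low, high) 95% CI from the final OLS fit
    data: pd.DataFrame


def recover_parameters(
    n_subjects: int = 65,
    trials_per_subject: int = 6,
    sigma_resid: float = 0.61,
    seed: int = 0,
    noise=None,
    alpha_in: float = 0.05,
    r_cut: float = 0.70,
    vif_cut: float = 5.0,
) -> RecoveryResult:
    """End-to-end parameter recovery: simulate, clean, estimate, refit.

    Generates an age/sex-stratified population, simulates
    ``trials_per_subject`` constant-work trials per subject across the
    six intensity anchors (33/66% of moderate, heavy and severe
    domains), estimates each trial's scHR through the cleaning pipeline
    and slope fit, then refits the prediction model by
    :func:`forward_select` over the candidate set {%RCP, age, sex,
    HRmax, VO2@5min, relative VO2max}.
    """
    from . import pipeline  # late import: pipeline composes all stages

    if trials_per_subject < 1:
        raise InputError("trials_per_subject must be >= 1")
    if n_subjects < 20:
        raise InputError("need at least 20 subjects for a stable refit")
    table = pipeline.simulate_step1_metrics(
        n_subjects=n_subjects,
        trials_per_subject=trials_per_subject,
        sigma_resid=sigma_resid,
        seed=seed,
        noise=noise,
    )
    model = forward_select(
        table,
        response="schr",
        candidates=["pct_rcp", "age", "sex", "hrmax", "vo2_5min", "vo2max_rel"],
        alpha_in=alpha_in,
        r_cut=r_cut,
        vif_cut=vif_cut,
    )
    X = sm.add_constant(table[list(model.selected_predictors)].to_numpy(dtype=float))
    fit = sm.OLS(table["schr"].to_numpy(dtype=float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    conf = {
        name: (float(ci[i + 1, 0]), float(ci[i + 1, 1]))
        for i, name in enumerate(model.selected_predictors)
    }
    return RecoveryResult(model=model, truth=PUBLISHED, conf_int=conf, data=table)
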