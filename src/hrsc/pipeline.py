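"""The two-step analysis pipeline.

Step 1 (development): simulate an age/sex-stratified cohort, six
constant-work trials per subject at the 33/66% anchors of the three
intensity domains, clean every trial, estimate per-trial scHR and
covariates, and refit the prediction equation by forward stepwise
regression.

Step 2 (validation): an independent cohort, three trials per subject
at the 50% anchors, project end-exercise HR from the fifth-minute HR
and the model-predicted scHR, and compare with the measured end HR by
Bland–Altman analysis.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import agreement, breathproc, io, ramptest, schrmodel, synthcardio, trialmetrics
from .errors import ConfigurationError
from .schrmodel import SchrModel, predict_schr
from .types import AgreementReport, sex_code

__all__ = ["PipelineConfig", "run_step1", "run_step2", "simulate_step1_metrics"]

#: per-domain exercise durations (s after onset) for the validation step;
#: severe-domain trials end early at exhaustion.
STEP2_DURATIONS = {"moderate": 900.0, "heavy": 900.0, "severe": 540.0}


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings, with documented defaults.

    ``seed`` feeds every random draw; per-subject and per-trial child
    seeds are derived deterministically from it.  Unknown keys are
    rejected by :meth:`from_dict`.
    """

    seed: int = 0
    n_subjects_step1: int = 65
    n_subjects_step2: int = 36
    trial_duration_step1: float = 540.0  # s after onset (9-min trials)
    noise: synthcardio.NoiseConfig = field(default_factory=synthcardio.NoiseConfig)
    kinetics: synthcardio.KineticsConfig = field(default_factory=synthcardio.KineticsConfig)
    truncate_negative_schr: bool = False
    sd_mult: float = 3.0
    bin_statistic: str = "mean"
    fit_start: float = 300.0  # s after onset where the scHR fit begins
    alpha_in: float = 0.05
    r_cut: float = 0.70
    vif_cut: float = 5.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "noise" in kwargs and isinstance(kwargs["noise"], dict):
            kwargs["noise"] = synthcardio.NoiseConfig(**kwargs["noise"])
        if "kinetics" in kwargs and isinstance(kwargs["kinetics"], dict):
            kwargs["kinetics"] = synthcardio.KineticsConfig(**kwargs["kinetics"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _child_seed(base: int, *indices: int) -> int:
    h = hashlib.sha256(("/".join(map(str, (base, *indices)))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _noiseless(noise: synthcardio.NoiseConfig) -> bool:
    return all(
        getattr(noise, f) == 0
        for f in ("hr_sd", "vo2_frac_sd", "vco2_frac_sd", "hr_day_sd")
    )


def simulate_step1_metrics(
    n_subjects: int,
    trials_per_subject: int = 6,
    sigma_resid: float = 0.61,
    seed: int = 0,
    noise: Optional[synthcardio.NoiseConfig] = None,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Simulate the development-step dataset and return the metrics table.

    One row per trial: estimated scHR plus the regression candidates
    (%RCP from the measured fifth-minute VO2, age, sex coding, HRmax,
    fifth-minute VO2, relative VO2max) and bookkeeping columns.
    """
    cfg = config or PipelineConfig(seed=seed)
    if noise is None:
        noise = dataclasses.replace(cfg.noise, sigma_resid=sigma_resid)
    anchors = ramptest.STEP1_ANCHORS
    population = synthcardio.generate_population(n_subjects, _child_seed(seed, 0))
    rows = []
    for si, subject in enumerate(population):
        for ti in range(trials_per_subject):
            domain, fraction = anchors[ti % len(anchors)]
            spec = ramptest.prescribe_trial(subject, domain, fraction)
            label = f"{domain[0].upper()}{1 if fraction < 0.5 else 2}"
            series, truth = synthcardio.simulate_constant_trial(
                subject,
                spec.target_vo2,
                duration=cfg.trial_duration_step1,
                seed=_child_seed(seed, 1, si, ti),
                noise=noise,
                kinetics=cfg.kinetics,
                truncate_negative_schr=cfg.truncate_negative_schr,
                trial_label=label,
            )
            clean = breathproc.clean_trial(series, sd_mult=cfg.sd_mult,
                                           statistic=cfg.bin_statistic)
            clean_meta = getattr(series, "meta", {})
            m = trialmetrics.compute_metrics(
                clean, subject, onset=clean_meta.get("onset", 180.0),
                fit_start=cfg.fit_start,
            )
            rows.append({
                "subject_id": subject.subject_id,
                "trial": label,
                "schr": m.schr,
                "schr_rel": m.schr_rel,
                "pct_rcp": m.pct_rcp,
                "age": subject.age,
                "sex": sex_code(subject.sex),
                "hrmax": subject.hrmax,
                "vo2_5min": m.vo2_5min,
                "vo2max_rel": subject.vo2max_rel,
                "hr_5min": m.hr_5min,
                "o2pulse_5": m.o2pulse_5,
                "o2pulse_9": m.o2pulse_9,
                "fit_r2": m.fit_r2,
                "true_schr": truth.true_schr,
                "pct_rcp_nominal": truth.pct_rcp,
            })
    return pd.DataFrame(rows)


@dataclass
class Step1Result:
    metrics: pd.DataFrame
    model: SchrModel
    config: PipelineConfig


def run_step1(config: PipelineConfig, outdir: Optional[str] = None) -> Step1Result:
    """Development step: simulate, clean, estimate, refit.

    With ``outdir``, writes the metrics CSV, the fitted model JSON and
    a run manifest (config hash and seed) so the artifacts can be
    reproduced bit-identically.
    """
    table = simulate_step1_metrics(
        n_subjects=config.n_subjects_step1,
        trials_per_subject=6,
        sigma_resid=config.noise.sigma_resid,
        seed=config.seed,
        noise=config.noise,
        config=config,
    )
    model = schrmodel.forward_select(
        table,
        response="schr",
        candidates=["pct_rcp", "age", "sex", "hrmax", "vo2_5min", "vo2max_rel"],
        alpha_in=config.alpha_in,
        r_cut=config.r_cut,
        vif_cut=config.vif_cut,
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "step1_metrics.csv", index=False)
        io.write_model_json(model, out / "step1_model.json")
        _write_manifest(config, out / "step1_manifest.json")
    return Step1Result(metrics=table, model=model, config=config)


def run_step2(
    config: PipelineConfig,
    model: SchrModel,
    outdir: Optional[str] = None,
) -> tuple:
    """Validation step: project end-exercise HR and measure agreement.

    Simulates three 50%-anchor trials per subject in an independent
    cohort; the measured end HR is the mean over the final minute of
    exercise, and the projection is evaluated at the temporal midpoint
    of that window so the two refer to the same instant.  Returns
    ``(AgreementReport, pairs_table)``.
    """
    population = synthcardio.generate_population(
        config.n_subjects_step2, _child_seed(config.seed, 10)
    )
    rows = []
    for si, subject in enumerate(population):
        for ti, (domain, fraction) in enumerate(ramptest.STEP2_ANCHORS):
            spec = ramptest.prescribe_trial(subject, domain, fraction)
            duration = STEP2_DURATIONS[domain]
            series, truth = synthcardio.simulate_constant_trial(
                subject,
                spec.target_vo2,
                duration=duration,
                seed=_child_seed(config.seed, 11, si, ti),
                noise=config.noise,
                kinetics=config.kinetics,
                truncate_negative_schr=config.truncate_negative_schr,
                trial_label=f"V-{domain}",
            )
            clean = breathproc.clean_trial(series, sd_mult=config.sd_mult,
                                           statistic=config.bin_statistic)
            onset = series.meta.get("onset", 180.0)
            # last minute actually covered by full 5-s bins
            t_end_min = (clean.t[-1] - onset) / 60.0
            hr_5 = trialmetrics.window_value(clean, "hr", 5, onset=onset)
            vo2_5 = trialmetrics.window_value(clean, "vo2", 5, onset=onset)
            hr_end = trialmetrics.window_value(clean, "hr", t_end_min, onset=onset, width=60.0)
            pct = trialmetrics.pct_rcp(vo2_5, subject.vo2_rcp)
            schr_est = predict_schr(pct, subject.age, subject.sex, model=model)
            hr_proj = agreement.project_hr(hr_5, schr_est, t_end_min - 0.5)
            rows.append({
                "subject_id": subject.subject_id,
                "trial": f"V-{domain}",
                "t_end_min": t_end_min,
                "hr_5min": hr_5,
                "pct_rcp": pct,
                "schr_est": schr_est,
                "true_schr": truth.true_schr,
                "hr_measured_end": hr_end,
                "hr_estimated_end": float(hr_proj),
            })
    pairs = pd.DataFrame(rows)
    report = agreement.bland_altman(
        pairs["hr_measured_end"].to_numpy(), pairs["hr_estimated_end"].to_numpy()
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pairs.to_csv(out / "step2_pairs.csv", index=False)
        io.write_report_json(report, out / "step2_report.json")
        _write_manifest(config, out / "step2_manifest.json")
    return report, pairs


def _write_manifest(config: PipelineConfig, path: Path) -> None:
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
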