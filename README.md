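# hrsc — the heart-rate slow component in constant-load exercise

During constant-work-rate exercise, heart rate does not settle at a
steady state: past roughly the fifth minute it keeps climbing at a
slow, near-linear rate — the **heart-rate slow component (scHR)** —
even while oxygen uptake (V̇O₂) holds steady. Anyone who prescribes
aerobic exercise by HR target inherits the problem: holding a fixed HR
forces a progressive cut in workload, and with it an undesired drop in
the metabolic stimulus the session was meant to deliver.

`hrsc` is a Python library for quantifying and predicting that drift.
It is aimed at exercise physiologists and sport scientists working
with breath-by-breath cardiopulmonary exercise test (CPET) data, and
provides:

* **`hrsc.synthcardio`** — a simulator of cardiopulmonary responses
  (age/sex-stratified populations, ramp tests with a mean response
  time, constant-work trials with mono-exponential primary kinetics, a
  linear slow component, irregular breath timing, injectable aberrant
  points) with full ground truth, so every stage is testable without
  access to raw laboratory data;
* **`hrsc.breathproc`** — the standard cleaning chain: windowed
  linear-fit outlier rejection (3 SD, transition-protected), 1-s
  linear interpolation, 5-s binning;
* **`hrsc.ramptest`** — maximal parameters (V̇O₂max, RERmax, HRmax),
  the MRT-corrected V̇O₂/power relation, and intensity prescription
  anchored to the exercise domains (moderate < GET < heavy < RCP <
  severe);
* **`hrsc.trialmetrics`** — per-trial measures: scHR as the OLS slope
  of HR vs time from minute 5, oxygen pulse, fifth-minute values,
  %RCP;
* **`hrsc.schrmodel`** — the scHR prediction equation and its
  refitting by forward stepwise regression with correlation/VIF
  screening;
* **`hrsc.agreement`** — dynamic HR-target projection and
  Bland–Altman validation.

## The model

For a subject of a given age (years) and sex (male = 0, female = 1)
exercising at a relative intensity expressed as a percentage of the
V̇O₂ at the respiratory compensation point (%RCP), the reference
equation is

    scHR (bpm·min⁻¹) = −0.0514 + 0.0240·%RCP − 0.0172·age − 0.347·sex

(`hrsc.PUBLISHED`; r² = 0.53, SEE = 0.61 bpm·min⁻¹ in the source
cohort). The drift-corrected HR target at minute *t* of exercise is

    HR@t = HR@5min + scHR · (t − 5)

## Worked example

```python
import hrsc

schr = hrsc.predict_schr(pct_rcp=100, age=35, sex="male")
print(f"predicted scHR: {schr:.4f} bpm/min")
for t_end in (5, 10, 15, 20):
    print(f"  minute {t_end:>2d}: HR target {hrsc.project_hr(140.0, schr, t_end):.1f} bpm")
```

prints

```
predicted scHR: 1.7466 bpm/min
  minute  5: HR target 140.0 bpm
  minute 10: HR target 148.7 bpm
  minute 15: HR target 157.5 bpm
  minute 20: HR target 166.2 bpm
```

i.e. a 35-year-old male at 100 %RCP drifts ~1.75 bpm each minute, so a
session opened at 140 bpm should let the target rise to ~166 bpm by
minute 20 to keep V̇O₂ constant.

The full two-step analysis runs end to end on synthetic data:

```python
cfg = hrsc.PipelineConfig(seed=1, n_subjects_step1=65)
res = hrsc.run_step1(cfg)            # 390 trials -> refit equation
print(res.model.selected_predictors)  # ('pct_rcp', 'age', 'sex')
print(round(res.model.beta_pctrcp, 4))  # 0.0235 (generating value 0.0240)

report, pairs = hrsc.run_step2(hrsc.PipelineConfig(seed=2), hrsc.PUBLISHED)
print(round(report.bias, 2), round(report.sd_diff, 2), round(report.pearson_r2, 3))
# -0.21 4.34 0.980  -> near-zero bias, tight limits of agreement
```

The `examples/` directory holds one short script per capability
(prediction/projection, trial cleaning, Step-1 refitting, Step-2
validation); each prints the numbers above with a line on what they
mean.

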