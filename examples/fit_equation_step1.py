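"""Development step: refit the scHR equation from a simulated cohort.

Simulates 65 age/sex-stratified subjects, six 9-minute constant-work
trials each (33% and 66% anchors of the moderate, heavy and severe
domains), cleans every trial, estimates per-trial scHR, and refits the
prediction model by forward stepwise regression with correlation/VIF
screening.  The recovered coefficients should sit close to the
generating (reference) ones.
"""
import hrsc

cfg = hrsc.PipelineConfig(seed=1, n_subjects_step1=65)
res = hrsc.run_step1(cfg)

print(f"{len(res.metrics)} trials from {cfg.n_subjects_step1} subjects")
print(f"selected predictors: {res.model.selected_predictors}")
print(f"  intercept  {res.model.intercept:+.4f}  (reference -0.0514)")
print(f"  %RCP       {res.model.beta_pctrcp:+.4f}  (reference +0.0240)")
print(f"  age        {res.model.beta_age:+.4f}  (reference -0.0172)")
print(f"  sex        {res.model.beta_sex:+.4f}  (reference -0.347)")
print(f"  r2 {res.model.r2:.3f}, SEE {res.model.see:.3f} bpm/min")
print("HRmax, VO2@5min and relative VO2max are screened out as collinear "
      "with %RCP/age when they try to enter.")
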