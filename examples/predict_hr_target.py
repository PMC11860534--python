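"""Predict the HR slow component and a drifting HR target.

The scHR equation gives the expected HR drift rate (bpm per minute,
past minute 5 of constant exercise) from relative intensity (%RCP),
age and sex.  Projecting it forward turns a fixed HR target into a
time-varying one that preserves the metabolic stimulus.
"""
import hrsc

# a 35-year-old male exercising at his respiratory compensation point
schr = hrsc.predict_schr(pct_rcp=100, age=35, sex="male")
print(f"predicted scHR: {schr:.4f} bpm/min")

# the same intensity for a 35-year-old female: a 0.347 bpm/min smaller drift
print(f"female at same intensity: {hrsc.predict_schr(100, 35, 'female'):.4f} bpm/min")

# dynamic HR target: 5th-minute HR of 140 bpm, projected through minute 20
for t_end in (5, 10, 15, 20):
    target = hrsc.project_hr(140.0, schr, t_end)
    print(f"  minute {t_end:>2d}: HR target {target:.1f} bpm")

print("Holding 140 bpm for 20 min would instead progressively cut the workload.")
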