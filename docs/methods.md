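# Methods

This note documents the models, estimators and numerical choices
behind `hrsc`, and what the synthetic-data generator does and does not
emulate.

## The measurement model

scHR is defined operationally: the OLS slope of HR against
time-in-minutes from the fifth minute of constant-load exercise to the
end of the trial (`trialmetrics.compute_schr`). No exponential or
bi-exponential kinetics are fitted — in the intended use the early
transient is excluded by construction and the late drift is treated as
linear. "At the fifth minute" quantities (HR, V̇O₂, oxygen pulse) are
means over the 30-s window ending at that minute, mirroring the 30-s
averaging convention used for maximal parameters; the width is a
parameter. Oxygen pulse is the ratio of the window means, not the mean
of per-breath ratios, which has lower variance under multiplicative
V̇O₂ noise.

The prediction model is a pooled OLS linear model of per-trial scHR on
%RCP, age and sex (male = 0, female = 1). Repeated trials within a
subject are treated as exchangeable observations; no random-effect
structure is imposed. `schrmodel.PUBLISHED` carries the reference
coefficients (−0.0514, +0.0240/%RCP, −0.0172/yr, −0.347 female).

## The synthetic-data generator

The generator is a first-class, tested component; it exists because
raw breath-by-breath cohorts of this kind are not publicly
deposited. It emulates:

* **Population structure** — three age groups (young < 36, middle
  36–55, elderly > 55) × sex with largest-remainder apportionment;
  defaults reproduce a 65-subject cohort (23/22/20 by age, 12/12/10
  female). Relative V̇O₂max is drawn per sex from N(51.0, 11.0) (male)
  / N(41.4, 7.1) (female), GET and RCP as fractions of V̇O₂max from
  N(0.621, 0.071) and N(0.845, 0.060). Truncation of the V̇O₂max
  draws is symmetric (±3.5 SD) so stratum means are unbiased. HRmax
  is centred on the age-predicted 208 − 0.7·age (SD 8), which
  cross-correlates HRmax with age the way real cohorts do — this is
  what lets the collinearity screen reproduce the expected selection
  behaviour. Body size (BMI, height by sex), resting V̇O₂
  (3.5 ± 0.3 mL·min⁻¹·kg⁻¹), the V̇O₂/power gain (10.2 ± 0.8
  mL·min⁻¹·W⁻¹) and the ramp mean response time (40 ± 10 s) are
  invented but configurable defaults.
* **Constant-work trials** — 180 s freewheeling baseline, an
  instantaneous power step, mono-exponential primary V̇O₂/HR kinetics
  with per-domain time constants (V̇O₂ 30/35/40 s, HR 35/40/45 s for
  moderate/heavy/severe), and from 300 s post-onset a linear HR slow
  component whose slope is the equation prediction at the trial's
  nominal %RCP plus a Normal(0, 0.61) residual. Breath timing is
  irregular (Uniform(2, 4) s). Measurement noise: HR 2 bpm per breath,
  gas channels 3% of signal, plus a per-trial HR offset of SD 1.8 bpm
  emulating day-to-day variability (chosen so the freewheeling
  within-subject CV lands in the observed low-single-digit range,
  ≈2.6%; an offset common to a whole trial cancels exactly in the
  slope and in measured-vs-projected differences).
* **Ramp tests** — a loaded baseline bout then a linear ramp; V̇O₂
  follows the ramp as a pure time delay (the subject's MRT) and
  plateaus at V̇O₂max for 30 s before exhaustion.
* **Aberrant breaths** — displacement of randomly chosen breaths
  outside the protected transition by ±k × local scale, the scale
  being the cleaning fit's residual SD floored at the channel's
  nominal noise so the displacement is meaningful on noiseless bases.

Two idealisations matter for interpretation. First, the primary
exponential is normalised to complete *exactly* 180 s after onset
(≈4–5 time constants, i.e. the ≥98% completion idealised to 100%).
Second, the simulator emits breaths exactly at the model's knots
(onset, onset+180, onset+300). Both exist so that the noiseless world
is exactly closed — the slope estimator, the cleaning chain
(remove → interpolate → bin) and the HR projection reproduce the
generated truth to 10⁻⁶ rather than to the size of an exponential
tail or an interpolation kink. Real data have no such knots; passing
the closure tests therefore demonstrates correctness of the
estimators, not that real transients are piecewise-exact.

The HR amplitude of a trial maps the V̇O₂ fraction of reserve into the
HR reserve with a sub-unity gain (0.85). This leaves the headroom
between fifth-minute HR and true HRmax that severe-domain exercise
shows in practice; with gain 1.0 the HRmax cap would clip the slow
component in severe trials and bias every downstream estimate.

Negative predicted slopes (low intensity, older women) are kept as-is
by default: a small early HR *decline* at steady state is plausible,
and censoring at zero would make the generating model unrecoverable by
linear refitting — the generator would contradict its own purpose as a
recovery test-bed. `truncate_negative_schr=True` restores the floor
for users who want strictly non-negative drift.

What the generator does **not** emulate: thermoregulatory and
catecholamine mechanisms, stroke-volume dynamics, cardiovascular drift
beyond 15 min, ectopic beats, and expert visual determination of
GET/RCP (synthetic subjects carry known thresholds).

## Cleaning

`remove_aberrant` fits one OLS line per channel to the baseline window
(onset − 180 … onset) and one to the steady-state window
(onset + 180 … end), single-pass, and deletes points whose residual
exceeds `sd_mult` (default 3) residual SDs; the residual SD uses the
n − 2 denominator. Nothing in the first 180 s of the transition is
ever deleted. Deletion is per channel (a breath removed from HR
survives in V̇O₂), represented as NaN and bridged by the 1-s linear
interpolation. Two textual conventions were resolved as: the 3-SD
criterion (not the 2.576-SD of a 99% prediction band) is the operative
default, and 5-s "mediation" is averaging, with median as an option.
Bins are aligned to absolute multiples of 5 s and timestamped at the
window centre, which keeps slope estimates on binned data unbiased.

Numerics: a window whose residual SD is below 10⁻⁹ × the channel scale
admits no removals (on an analytically flat noiseless window the 3-SD
rule would otherwise flag round-off). On long (15-min) noiseless
trials the single-line steady-state fit has structured residuals near
the window edges and may flag a handful of early-steady breaths; these
sit outside every measurement window, so no derived quantity is
affected, and with realistic noise the effect vanishes.

## Ramp analysis and prescription

The MRT is the time shift between the moment ramp power passes the
baseline power and the moment the fitted ramp V̇O₂ line passes the
measured baseline steady state (clamped at 0); it is invariant to the
ramp rate by construction. Intensity targets are anchored within
domains (moderate: rest + f·(GET − rest); heavy: GET + f·(RCP − GET);
severe: RCP + f·(V̇O₂max − RCP)), and power is obtained by inverting
the linear V̇O₂/power relation. Above GET an optional one-parameter
slow-component correction (`sc_gain`, mL·min⁻¹·W⁻¹, default 0)
steepens the effective gain, standing in for more elaborate published
corrections without reproducing any particular one.

## Model refitting

`forward_select` is forward stepwise OLS: at each step the candidate
with the smallest partial-F p-value below `alpha_in` (0.05) enters;
after each entry, pairwise |Pearson r| > 0.70 or VIF > 5 among the
included predictors discards the later entrant from the model and
from further candidacy. The SEE uses the n − p − 1 denominator. A
degenerate-residual guard stops selection once the fit is numerically
perfect (SSR ≤ 10⁻¹⁰·n·var(y)), since partial-F p-values on zero
residuals are round-off noise. The final model is re-estimated by
plain OLS on the surviving set; an invariant asserts no retained pair
violates the correlation screen.

## Validation

`project_hr` implements HR@t = HR@5min + scHR·(t − 5). In `run_step2`
the measured end HR is the mean over the final minute of binned data,
and the projection is evaluated at that window's temporal midpoint so
both refer to the same instant; with the end-time convention instead,
a last-minute-mean measurement carries a systematic −scHR/2 offset.
Bland–Altman differences are oriented measured − estimated (positive
bias = under-prediction), limits of agreement are bias ± 1.96 SD
(exact identities, asserted), and the z-score is bias/sd_diff.
Within-subject CV is 100·SD/mean per subject, summarised as mean ± SD
across subjects. Step-2 trials run 15 min in the moderate and heavy
domains and 9 min in the severe domain (exhaustion), giving a mean
duration near 13 min.

## Problem sizes and determinism

Every stochastic routine takes an integer seed; identical inputs give
bit-identical outputs (child seeds are derived by hashing, kept below
2³¹). The test suite exercises the full design at its native size
where that is cheap (65 × 6 trials ≈ 0.5 s) and uses 200 seeded
replicates for coverage checks, 10⁴ trials for unbiasedness, and 10³
simulations for the selection null — sizes at which the binomial/CLT
bands in the assertions are meaningful.

## Known limitations

* The linearity of the slow component is assumed, not tested, beyond
  15 min; cardiovascular drift proper (>30 min) is out of scope.
* Pooled OLS ignores within-subject correlation; coefficient SEs in
  the refit are mildly optimistic for real repeated-measures data.
* The generator's residual structure is Gaussian and homoscedastic;
  real scHR residuals may be neither.
* GET/RCP are taken as known; threshold-detection error is not
  modelled.
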