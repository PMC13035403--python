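# Methods

This note documents the models and procedures implemented in
`irilearn`, the conventions adopted where the underlying procedures were
underdetermined, and what the synthetic-data tests do and do not show
about real recordings.

## Conditioning schedules

A protocol is a sequence of trials, each consisting of a cue
(0.25 s), a trace period (1 s), probabilistic reward delivery at cue
onset + 1.25 s, and a fixed 3-s consumption period. Intertrial
intervals are i.i.d. uniform on `mean ± jitter·mean` (jitter 0.2 for
all experimental groups except the fixed 3,600-s group). Conventions:

- **One ITI precedes every trial, including the first of a session.**
  This makes "ITIs experienced before trial L+1" equal to L+1, so total
  time-to-learn after trial L is `L·4.25 + (L+1)·mean_ITI` at zero
  jitter. The cue–shock protocols make the leading interval explicit
  (a 300-s pre-session baseline); for the cue–reward groups it is a
  modeling choice, exposed through `pre_session_delay`.
- **The consumption period is scheduled on omission trials too**, so
  partial reinforcement changes the IRI without touching the ITI or the
  inter-cue interval: `IRI = (mean_ITI + 4.25)/p`.
- **Sessions are concatenated without a modeled gap.** Event times
  double as cumulative conditioning time, the clock used for all
  time-to-learn analyses; overnight intervals are outside the model.
- Distractor CS− cues follow an exponential renewal process (mean 60 s)
  restarted within each inter-trial gap; background rewards of a second
  identity are placed by sequential uniform spacing (mean 180 s ± 20%)
  measured from the previous reward delivery of any identity. Both are
  guaranteed to fall strictly outside trial blocks; impossible packing
  raises a schedule-infeasibility error rather than silently dropping
  events.
- Time is in seconds (double precision); trial indices are 1-based.

## Learned-trial detection

Per-trial cue-evoked licking is the count of lick onsets in
`[cue, cue+1.25)` minus the count in `[cue−1.25, cue)`. The learned
trial is detected from the cumulative sum S of this series (S₀ = 0):

1. Draw a diagonal from (0, 0) to (n, Sₙ).
2. Compute the vertical distance `dᵢ = line(i) − Sᵢ` at every trial.
   Distances are vertical rather than perpendicular because the axes
   carry different units.
3. The learned trial is the first trial whose |dᵢ| reaches 75% of the
   maximum |dᵢ| (ties break to the earliest trial).
4. If the signed distance there is negative — the diagonal lies *below*
   the curve, meaning responding was decreasing at that trial — the
   diagonal's endpoint is re-anchored to (L, S_L) and the rule
   re-applied, at most n times. A flat or perfectly linear series (all
   distances ≈ 0), or a re-anchoring loop that fails to converge, is
   reported as degenerate with no learned trial.

The magnitude-based distance is deliberate: with a signed maximum the
re-anchoring branch could never fire, because the detected trial would
always satisfy d ≥ 0.75·max > 0. Taking the maximum of |d| lets
tapering series (steep rise, then decline) place the first detection on
the decreasing limb, which is exactly the case the re-anchoring rule
exists to fix.

**Abruptness** is the distance at the learned trial normalized by the
final diagonal's terminal height (top of the diagonal = 1).

**Known lead bias.** For an ideal step at trial c in an otherwise flat
series, the distance grows linearly up to the step, so the 75% rule
fires at ≈ 0.75·(c − 1): about a quarter of the change-point trial
*early*. Planted-change-point recovery to ±2 trials is therefore only a
meaningful expectation in the early-learning regime (c ≲ 8), which is
the regime the synthetic cohorts emulate (the long-ITI groups learn in
~9 trials). For late change points the systematic lead dominates, and
tests pin detector/oracle equivalence rather than proximity to the
planted trial. The threshold fraction is exposed
(`threshold_frac`) for sensitivity analyses.

The **dopamine learned trial** runs the same detector with the initial
diagonal anchored at 1.5× the behavioral learned trial (clamped to the
series length), compensating for cue responses that decline with
extended training. The **omission-dip trial** runs the detector on the
negated omission-response series to find the negative-going inflection.

Non-learners are animals without a > 0.5-Hz session-mean increase in
cue-evoked lick rate in at least two sessions. "Trial 1" is re-anchored
to the first rewarded trial consumed within 5 s (except under partial
reinforcement, where omission counting requires the raw trial index).

## Photometry

dF/F is computed session-wide: ordinary least squares maps the 405-nm
isosbestic channel onto the 470-nm signal channel, and
`dF/F = 100·(f470 − fitted405)/fitted405`. A constant 405 channel is a
singular fit and raises, except in the fully degenerate case where both
channels are constant (the intercept-only limit; dF/F ≡ 0). Responses
are trapezoidal AUCs on the native ~120-Hz grid with half-open windows:

- **Cue:** 0.5 s after cue onset minus the 0.5 s before it.
- **Reward:** 0.5 s after the first lick onset following delivery
  (delivery time itself when a lick contact spans it, or as a flagged
  fallback when no lick occurs within 5 s), minus the same trial's
  pre-cue baseline. The baseline is measured relative to cue onset, not
  re-measured at the lick anchor.
- **Omission:** 2-s window from the withheld-reward time (cue + 1.25 s)
  minus a 2-s pre-cue baseline; wider windows capture the slower dip
  kinetics.
- **Peaks:** window maximum minus baseline-window mean.

Per-animal normalization divides by the mean of the three largest
reward responses; omissions use a separate normalizer measured in 2-s
windows to match the dip measurement. Normalization is invariant to
global gain, and the AUC operators are linear in the trace.

## Learning models

All three models are driven by the same event schedules and read out
identically: the per-trial association quantity is compared against a
threshold, and the learned trial is the first crossing.

**Microstimulus TDRL** (dt 0.25 s). Each cue or reward launches a
memory trace decaying by d per step; m Gaussian basis functions
(width σ, centers equally spaced on (0,1], amplitude weighted by trace
height) encode the trace, so the full ITI is represented by states that
can acquire value. TD(λ) with accumulating eligibility traces updates
the weights; the per-trial quantity is the maximum value between cue
onset and reward, and the dopamine proxy is the prediction error at cue
and reward steps. Best-fit defaults: threshold 0.3, α 0.1, γ 0.99,
m 3, d 0.9, λ 0.99, σ 0.08. The scaled variant replaces α with
`1 − exp(−k·IRI)` (best fit k = 3×10⁻⁴).

**SOP** (dt 0.25 s). Stimulus nodes hold element fractions in
inactive/A1/A2 states; presentations move `p1·pI` into A1, decay moves
`pd1·pA1` to A2 and `pd2·pA2` back to I each step. The association
changes by `ΔV = pA1_cs·(L⁺·pA1_us·r1 − L⁻·pA2_us·r2)`. After
learning, cue presentations drive reward elements I→A2 in proportion to
V (clipped to [0,1]; the proportionality constant is taken as 1, an
open choice). Presentations occupy the single step containing their
onset. The constraint pd1 > pd2 per node is enforced by default. Best
fit: threshold 0.1, pd1_us 0.25, pd2_us 0.1, pd1_cs 0.1, pd2_cs 1e-4.

**ANCCR** (dt 0.2 s). Eligibility traces decay with time constant
T = k·IRI. The retrospective association updates at rewards with
learning rate `α = 1 − (1 − α₀)^(IRI/dt)` — the rate forced by
requiring the retrospective association and the continuously updated
baseline rates to integrate the same span of past experience, and the
source of proportional IRI scaling. The Bayes-rule conversion and net
contingency are implemented in simplified form:

```
M→cr = M←cr · M←r / M←c
NC   = w·(M→cr − M←r) + (1−w)·(M←cr − M←c),   w = 0.5
```

with a floor guard on the cue baseline divisor. Learning is identity
specific: background rewards of a second identity maintain their own
trace and baseline but do not update the cue–sucrose association. The
dopamine proxy is NC at cues and NC plus an innate meaningfulness of 1
at rewards. Best fit: threshold 0.4, α₀ 4×10⁻⁵, k 0.5. The
implementation is event-driven — eligibility decay and the geometric
baseline relaxation between events are applied in closed form on the dt
grid — which is exact and makes hour-long ITIs cheap.

At the best-fit parameters the three models separate categorically, as
the test suite asserts: ANCCR's simulated trials-to-learn scale as
IRI^(−1.0±0.15) with a time-to-learn coefficient of variation < 0.25
across the 30–600-s conditions, while TDRL (both variants) and SOP need
more conditioning time at longer ITIs (positive regression slope).

## Model comparison

Simulations run for the trial counts the experimental groups
experienced (800/400/88/48/16 for 30/60/300/600/3,600-s ITIs), 20
iterations each. Fit quality is the residual sum of squares of log10
trials-to-learn against the experimental group means; by default the
RSS is computed per iteration and averaged (meanRSS), with a
mean-of-simulations strategy available — the original aggregation is
ambiguous and neither is asserted. Censored iterations (no crossing)
contribute the simulated trial count + 1, flagged, so non-learning
parameter sets still rank. `AIC = 2k + n·ln(meanRSS)` is reported at
k = 0; n defaults to 52, the learner animals across the five groups,
and is configurable since the published value is not recoverable.
Relative weights are `exp(−0.5·(AIC − AIC_min))`. The full published
sweep grids are cluster-scale; desk-scale runs subsample them (the
acceptance suite uses an 18-combination, 5-iteration sweep and checks
that a ground-truth parameter set injected into the grid is ranked
first on data it generated).

## Scaling regression

Base-10 ordinary least squares of log trials-to-learn on log IRI (the
published intercept is only consistent with base 10). The dopamine
"fit" across two groups is the exact line through two points.
Predictions are `10^(intercept + slope·log10 IRI)`. Note one rounding
artifact: evaluating the printed dopamine coefficients (−1.0359,
3.4338) at IRI 128.5 s yields 17.75, which prints as 17.7 rather than
the published 17.8; the original prediction evidently used unrounded
coefficients. Comparisons against printed predictions therefore allow
half a unit in the last printed digit plus a small coefficient-rounding
allowance.

## Synthetic data: what it does and does not show

The generators produce the *structure* the analyses consume — Poisson
baseline licking, sub-500-ms-gap consumption bouts, anticipatory
licking stepping (or ramping) at a planted change point, photometry
transients as difference-of-exponentials kernels (rise 0.05 s, decay
0.5 s, chosen so 0.5-s windows capture most of the transient mass) with
a shared low-frequency artifact and independent channel noise. Defaults
emulate the rapid-learning long-ITI cohorts: baseline 0.3 Hz,
anticipatory 4 Hz, change point at trial 8 (the 600-s group's observed
8.8 ± 0.6). Amplitude trajectories are caller-supplied so tests can
plant steps, sigmoids, or the qualitative pattern of reward responses
rising before cue responses.

Passing tests on this data show that the pipeline recovers known ground
truth under the stated statistical model; they do not validate the
model against real behavior. Known omissions: licking
autocorrelation and satiety drift; spout-grab artifacts (long contacts);
bleaching and hemodynamic trends beyond the shared artifact term;
sensor kinetics beyond a fixed kernel; video-based freezing data.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (numpy Generator);
same seed and configuration give byte-identical schedules, data, and
simulation results. The default test suite and the acceptance script
use 20 iterations per ITI condition for ANCCR (which is event-driven
and fast), 10 for the step-simulated TDRL/SOP time-slope checks, 50
cohorts for recovery properties, and 1,000 random series for
detector/oracle equivalence — sizes chosen to keep the whole suite
around a minute while leaving the stochastic acceptance margins wide.
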