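# Methods

## The two-process state-space model

The pipeline models the horizontal amplitude component of primary
saccades in a paradigm where, on adaptation trials, a first candidate
stimulus appears at ±2° horizontal eccentricity upon saccade detection
(150 ms), followed after a 200 ms gap by a second candidate at the
opposite location (150 ms). Depending on condition, the perceptual task
(a 4-alternative gap discrimination) attaches to the first or the second
candidate, and one of the two may be omitted. `loc_n` denotes the signed
horizontal location of the task-relevant candidate on trial *n*; it is 0
on baseline and retention trials, where no candidates are shown.

Per trial the predicted amplitude is a weighted mixture of two learning
processes:

    horAmp_n    = w · strategic_n + (1 − w) · gradual_n
    strategic_n = loc_{n−1} · d                       (full, voluntary re-aim)
    gradual_n   = horAmp_{n−1} − r (horAmp_{n−1} − loc_{n−1} d)   (partial correction)

with `w ∈ [0, 1]` the strategic weight, `r ∈ [0, 1]` the gradual learning
rate, and `d ∈ {−1, +1}` choosing the task-relevant (+1) or
task-irrelevant (−1) candidate as adaptation target. `horAmp_1 = init`.
The recursion runs in pure simulation mode: the previous *model output*
feeds the next update. A teacher-forced variant
(`model.one_step_ahead`) exists for sensitivity analyses and is off by
default.

### Identifiability

Substituting the process equations into the mixture gives, for every
location sequence,

    horAmp_n = a · horAmp_{n−1} + (1 − a) · loc_{n−1} d,   a = (1 − w)(1 − r).

The mapping from parameters to predictions — and hence any least-squares
or Gaussian-likelihood objective — factors through `a`. Consequences:

* `d` and the **effective learning rate** `1 − a` are identifiable, and
  simulation shows they are recovered well under the study's conditions
  (direction recovered in 100 % of 288 simulated fits at 0.5° noise;
  median absolute effective-rate error ≈ 0.08).
* `w` and `r` individually are **not** identifiable: any `(w, r)` with
  `(1 − w)(1 − r) = â` predicts the identical series, so the multi-start
  winner lands arbitrarily on that ridge. Since both factors are at most
  1, the ridge does bound each parameter (`w, r ≤ 1 − â`), which is why
  recovery looks good for small generative `w` and `r` and degrades for
  large ones. The same collapse holds under teacher forcing. `ModelFit`
  therefore reports `effective_rate` alongside the raw `(w, r)` of the
  winning restart, and interpretation of `w` and `r` in isolation is
  discouraged.

### Fitting

`init` is fixed to the mean observed amplitude over usable baseline
trials (≈ 0 after baseline correction), never fitted. `d` is enumerated
exhaustively. For each sign of `d`, 101 starting values of `r` (evenly
spaced on [0, 1] plus a small seeded jitter; `w` always starts at 0.5)
seed a bounded L-BFGS-B minimisation of the residual sum of squares over
`(w, r) ∈ [0, 1]²` with tolerance 1e−8. The winner minimises
`BIC = n ln(rss/n) + k ln(n)` (Gaussian profile likelihood; `k = 3` for
`w, r, d`; a perfect fit maps to −∞ so it wins every comparison). Since
`n` and `k` are common to all restarts, BIC ranking equals RSS ranking;
BIC is still reported per restart for provenance. The model is fitted to
baseline + adaptation trials only. Excluded trials are masked out of the
objective but the recursion covers the full design-ordered sequence (the
participant experienced those trials). A fit that does no better than
the constant model is flagged degenerate with a warning: flat data carry
no learning signal at all.

Note a subtlety of the literal equations: with `loc = 0` the recursion
still pulls the output toward 0 at rate `1 − a`, so a nonzero `init`
decays during baseline rather than persisting. After baseline correction
`init ≈ 0` and the distinction is invisible; the implementation keeps the
literal behaviour.

## Synthetic data

The generator is the pipeline's test bed: every downstream stage is
validated against its known ground truth. Its defaults are the emulated
study's conditions; they are not tuning knobs.

* **Design**: 350 trials (50 baseline, 200 adaptation, 100 retention),
  set break after every 50th trial, candidates at ±2°, saccade target at
  10° vertical eccentricity, 1,000 Hz sampling. Timing constants
  (150/200/150 ms; 1,500 ms saccade and response timeouts) are carried as
  design metadata, as is the ~30 ms net viewing-time deficit of the
  first candidate (which affects no computation).
* **Amplitudes**: forward model + i.i.d. Gaussian motor noise, default
  `noise_sd = 0.5°` — a plausible trial-to-trial scatter for ~10°
  saccades, chosen once; the emulated study does not state trial-level
  variability, so this default is a free choice, not an estimate of the
  original data. Running the recursion over all 350 trials makes
  retention decay toward zero at rate `a` per trial; in particular a
  pure-strategic cohort (`w = 1`) shows no retention after-effect.
* **Sign convention**: positive x points toward the first candidate.
  Everything is simulated in a canonical plus-side frame and reflected
  when `first_candidate_side="minus"`, so a side flip under a fixed seed
  mirrors every signed output exactly — the basis of the sign-convention
  audit.
* **Traces**: a single saccade embedded in fixation epochs. The
  displacement time course is a regularised incomplete beta function
  (velocity profile Beta(α, β) with α + β = 6), whose skew is solved so
  that the fraction of displacement accumulated before the velocity peak
  equals `acc_frac` (clipped to [0.02, 0.98] where the profile
  degenerates); horizontal and vertical components share the time course,
  so the 2-D speed is unimodal. The saccade onset is phase-shifted so the
  continuous-time peak falls exactly on a 1 ms sample. Default saccade
  duration 50 ms and latency 200 ± 50 ms are realistic for 10° saccades
  and configurable; the profile family is a modeling choice, not a claim
  about real saccade dynamics.
* **Responses**: `P(correct | e) = 0.25 + (asymptote − 0.25) · g(|e|)`
  with `g(e) = 2 / (1 + exp(e / scale))`, which equals 1 at zero retinal
  error and decays monotonically to 0. Defaults: asymptote 0.9, scale 1°.
* **Artifacts**: blink / timeout / hypometric markers injected
  independently per trial at configurable rates (default 0), writing
  exactly the fields the exclusion rules read.

What the generator does **not** emulate: saccadic reaction-time
structure, main-sequence velocity scaling, trajectory curvature, secondary
corrective saccades, set-break amplitude jumps (available as an optional
offset, default 0), oculomotor drift, or measurement noise of a real eye
tracker. Passing tests demonstrate the pipeline's internal correctness
and recoverability under these idealised conditions, not performance on
recorded data.

## Preprocessing

Saccade detection uses central-difference velocities on boxcar-smoothed
positions (default 5 ms window) and marks samples whose 2-D speed exceeds
30 deg/s or whose speed derivative exceeds 8,000 deg/s²; contiguous runs
of at least 4 ms whose peak speed reaches the speed threshold become
events (the publicly documented defaults of the common video-oculography
parser; all configurable). The primary saccade is the first event after
target onset ending more than 2° from fixation; the secondary saccade is
the first event between primary offset and 60 ms after second-candidate
onset, discarded if its endpoint indicates a return to screen center
(vertical < 5°) or an outlier (|horizontal| > 6°).

Exclusion rules (hypometric vertical amplitude < 50 % of target distance,
|horizontal amplitude| > 6°, blink between target and first-candidate
onset, saccade timeout at 1,500 ms, > 2° fixation deviation in
[−20, 80] ms around target onset, missing response within 1,500 ms on
adaptation trials) are all evaluated per trial; a trial collects every
violated reason code. A rule whose inputs are missing marks the trial
`technical`; when no primary saccade exists, the saccade-measurement and
response rules are vacuously skipped instead (timeout trials required no
judgment). The blink criterion itself (how a blink is identified in a
trace) is configuration, not science: the generator writes an explicit
marker.

Baseline correction subtracts the mean over usable baseline trials,
identically for amplitudes and for acceleration/deceleration
displacements; it is exact and idempotent by construction.

## Kinematic split

The 2-D speed `sqrt(vel_h² + vel_v²)` is maximised over the detected
saccade segment; displacement before/after the peak sample (computed from
positions, so the phases sum to the total exactly) gives the
acceleration- and deceleration-phase horizontal displacement. The peak
sample belongs to the acceleration phase; ties break to the earliest
sample and are flagged. Unlike the detector, the split uses *unsmoothed*
velocities by default: a boxcar window biases the peak location by
several samples when the peak sits near the saccade's steep edges, which
distorts the split by up to ±0.15 for extreme skews, whereas without
smoothing the recovered fraction is within 0.004 of the generative value
across `acc_frac ∈ {0.1, …, 0.9}` (noiseless traces at 1 kHz). Both
window sizes are configurable.

## Summaries

The asymmetric moving average restarts in each 50-trial block (widths 2,
4, then 6 trials, right-sided, truncated at block end, stride 1, NaN
skipped) and is verified against literal window enumeration. Block
statistics use the two-sided 95 % t-interval over a block's usable trials
(the interval construction is our choice; a block of identical values
yields a zero-width interval). Cohort tables report, per condition, the
group mean with its across-participant t-interval and counts of
participants by significance × direction. Psychometric summaries bin
|retinal error| and report per-bin proportion correct with Wilson 95 %
intervals plus the Spearman rank correlation of accuracy against bin
center as the monotone-decline statistic; empty bins are reported as
missing.

## Problem sizes

The recovery study uses 24 synthetic participants per cell over
`w ∈ {0.1, 0.35, 0.65} × r ∈ {0.1, 0.3} × d ∈ {−1, +1}` at 0.5° noise
with 101 restarts (≈ 1 minute on one CPU); oracle comparisons use 200
random parameter draws (forward model) and 100 random blocks (moving
average); kinematic recovery runs a 9-point `acc_frac` grid. These sizes
give stable medians and worst-case statistics while keeping the whole
validation run near a minute.

## Known limitations

* `w` and `r` are reported but only their combination `(1−w)(1−r)` is
  statistically meaningful (see Identifiability); cross-condition
  comparisons should use `effective_rate` and `d`.
* The detector is a generic threshold parser, not a re-implementation of
  any proprietary algorithm; absolute event boundaries differ from
  hardware parsers at the millisecond scale.
* The trace generator's shared horizontal/vertical time course makes
  saccades straight; curvature-related effects cannot be studied with it.
* Retention dynamics follow the literal model recursion (decay at rate
  `a`); alternative retention models (e.g. distinct retention rates) are
  out of scope.
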