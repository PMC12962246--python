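# Methods

This note records the models, conventions and calibrations behind the
package, the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Trial schedule

A trial is: 1000 ms central fixation, then 13 faces at a 300-ms SOA, each
visible 600 ms while drifting 60 px laterally (successive faces drift in
opposite directions; at most two visible at once), then 2000 ms of fixation
tail — 7200 ms in total. Face k's onset is `1000 + (k−1)·300` ms; the
critical face sits at position 5–8, so its onset is 2200–3100 ms and at
least 4100 ms of recording follow it, comfortably covering the 0–2500 ms
analysis window. The drift direction of face 1 is random per trial (only the
alternation is fixed by the paradigm). Schedule arithmetic is exact and
closed-form; stream-tail durations quoted elsewhere that disagree with this
arithmetic are not used.

## Synthetic data generator

The generator's job is to emulate the statistical structure the analysis
assumes, not the physiology in detail.

**Pupil.** Per trial: a participant-specific baseline (N(4000, 400²) a.u.,
EyeLink-like arbitrary units), a linear drift with slope N(0, (20 a.u./s)²),
a slow AR(1) wander (coefficient 0.995 at 100 Hz, stationary SD 180 a.u. —
the dominant noise source in video pupillometry), and a condition-locked
response kernel. The kernel is a smooth Erlang-like bump
`u² exp(2(1−u))`, `u = (t−latency)/rise`, zero before `latency`, peaking at
`latency + rise`; a boxcar variant provides a constant injected effect for
recovery checks. Kernel amplitudes decompose into a population mean, a
between-participant SD and a between-trial SD.

**Defaults (the study conditions).** Target: latency 300 ms, rise 1400 ms,
amplitude 160 ± 60 (between) ± 40 (within) a.u. — early, large and
sustained. Familiar: latency 600 ms, rise 700 ms (peak ≈ 1.3 s), amplitude
40 ± 20 ± 40 a.u. Controls: no kernel. The amplitude/noise scales were set
analytically to the *moderate effect size* regime the paradigm reports:
with trial-level pupil SD ≈ 170 a.u. after baselining, the familiar effect
gives per-trial Cohen's d ≈ 0.23 for pupil size and ≈ 0.2–0.3 for its
smoothed rate; with 48 familiar vs 96 control trials, a one-tailed α = .05
test then detects a third to a half of participants — matching the
published detection-rate range (18.5–55.2%) rather than a ceiling or floor.

**Gaze.** Constrained design: AR(1) fixation jitter (SD 8 px) plus, on
target trials, a pursuit bump rising from 400 ms after critical onset to a
peak (100 px) near 990 ms; a random ~17% of participants are "saccade
strategists" who instead jump ~400 px and hold. Free design: a weaker
pursuit template (25 px) plus a sinusoidal stream-following oscillation
(15 px, period 2 × SOA, signed by the first face's direction). Familiar
trials carry no gaze template by default (the constrained-gaze finding);
`familiar_gaze_scale` turns one on for power-testing the gaze LOO path.

**Blinks / missing data.** Poisson blink onsets (0.1 Hz, 200 ms) blank both
channels. The generator can emit a 1000-Hz dialect to exercise the
downsampler; the default output is the 100-Hz analysis grid directly.

**What the generator does not emulate:** luminance responses to individual
faces, saccade kinematics and microsaccades, vertical gaze, pupil
foreshortening, or session-level nonstationarity beyond linear drift.
Passing the synthetic validation therefore shows the *machinery* is
correct and calibrated under the assumed structure — not that real
recordings satisfy that structure.

## Preprocessing conventions

* Downsampling: non-overlapping 10-sample bin means over valid samples,
  timestamped at bin start; a bin with more than 50% invalid samples is
  invalid.
* Epoch grid: half-open [0, 2500) ms, 250 samples at bin starts.
* Baseline: mean of the 5 grid samples immediately before critical onset;
  undefined if any is invalid. Undefined baselines and baselines more than
  2 SD from the mean are excluded, jointly for gaze and pupil. The 2-SD
  reference population is per participant by default (a.u. scales are
  recording-specific; pooling would conflate calibration differences), with
  a pooled option.
* Rate of change: first difference (first sample undefined), centered
  25-sample boxcar, truncated at the edges; a smoothed sample is invalid
  when more than half of its window's differences are invalid, otherwise it
  averages the valid ones. No blink interpolation anywhere — missing
  samples drop listwise in the per-sample fits.
* Accuracy: constrained design — signed gaze at critical offset
  (onset + 600 ms) ≥ 50 px for targets, |·| < 50 px for non-targets (the
  threshold is configurable; the boundary counts toward the target rule);
  free design — keypress match.

## Per-sample mixed models

Conditions enter as control (pooled control1 + control2, the reference),
familiar and target; pooling at the factor level operationalises
"average of the controls" for trial-level fits. The default random
structure is a by-participant intercept plus condition slopes, estimated by
maximum likelihood via statsmodels `MixedLM`; per-coefficient inference is
Wald z. Samples whose fit does not converge are flagged, refit with the
intercept-only engine for a usable point estimate, excluded from the FDR
family, and break cluster runs.

The intercept-only engine is an exact profiled-ML solver: for a variance
ratio λ = τ²/σ², the GLS solution and profile likelihood are closed-form in
per-group sufficient statistics, leaving a 1-D bounded optimisation over
log λ (with the λ = 0 boundary always checked). It matches `MixedLM` ML
estimates to ~1e-3 and is two orders of magnitude faster — this is what
makes the bootstrap power loop (≈ 25 000 fits per 100 iterations) and the
100-replicate null calibration tractable. Tests keep the two engines as
mutually checking routes.

FDR families are one per measure × contrast (matching how results are
reported per contrast), BH step-up at q = .05. Clusters are maximal runs of
≥ 200 ms of consecutive significant samples; a cluster's `end_ms` is the
last significant sample plus one grid step (half-open), so printed windows
like "800–1570 ms" are representable. Interaction fits add design
(constrained = 0, free = 1) and condition × design terms with random
condition slopes; releveling to a familiar reference refits the same model
(identical log-likelihood), which the tests assert.

## Leave-one-out detection

The reference trace is the unweighted across-participant mean of per-
participant familiar-minus-pooled-control traces (weighting by trial count
is deliberately off: participants are the exchangeable unit). Localization
takes the oriented maximum within the window, ties to the earliest sample.
The focal test is a pooled-variance Student t over trial-level values at
the localized sample — familiar (n ≈ 48) vs pooled control (n ≈ 96) — with
a one-tailed p in the predicted direction and an ε-guard (1e-12) on the
pooled variance so that perfect separation is detected rather than
undefined. Trial-level operands are the only reading consistent with
per-participant confidence intervals; Welch's t is a defensible alternative
but the pooled form is the classical "independent samples t-test".

Window orientation is configuration: the orienting window (0–1000 ms) is
oriented so gaze-toward-familiar scores positive and the avoidance window
(1000–2500 ms) so gaze-away scores positive. The source description of
which sign was computed in the first window is internally inconsistent, so
the orientation is a named parameter (`WindowSpec.direction`,
`orienting_direction` in the pipeline config) rather than a hard-coded
choice. Participants with fewer than 2 valid trials in either group count
as not detected but stay in the denominator (conservative; configurable).

## Bootstrap power

Resampled duplicates become distinct pseudo-participants. The per-iteration
model is the fast random-intercept engine on familiar vs pooled control
(the full random-slope model is available behind a flag but is ~100× the
cost inside a 1000 × 250-fit loop). The hit rule is expressed in
milliseconds because grids differ across studies: the default demands
strictly more than 200 ms of consecutive uncorrected p < .05 (the "more
than 5 consecutive samples (200 ms)" reading); the inclusive reading is
selectable. No FDR inside the hit rule. A degenerate resample (all copies
of one participant) is recorded as a non-hit with a warning.

## Validation studies and problem sizes

The acceptance studies (in `msvp.studies`, consumed by both
`tests/test_acceptance.py` and `scripts/acceptance.py`) use: 100 null
replicates at 29 participants with the familiar kernel zeroed (LOO
detection rates expected in [.02, .08]; ≥ 90% of replicates without a
spurious familiar cluster, evaluated with the intercept-only engine on a
50-ms grid — the coarser grid and fast engine keep 100 full-pipeline
replicates to a few minutes while leaving the calibration question
unchanged); one 29-participant recovery run with a 60-a.u. boxcar on
800–1600 ms (plateau β within 15%, cluster Jaccard ≥ 0.5); ten
29-participant replicates of the calibrated default for the detection-rate
bracket (expected mean in [0.3, 0.7], monotone in amplitude under common
random numbers); and 100 bootstrap iterations at N = 5 on a large (300
a.u.) sustained effect (hit rate ≈ 1). Smaller seeds-fixed versions of the
same checks run inside the unit suite.

## Numerical details and edge cases

* All randomness flows from `numpy.random.SeedSequence` spawns of one base
  seed; identical config + seed reproduces every table byte-for-byte.
* λ is profiled on [1e-8, 1e5] with the zero boundary checked explicitly;
  a residual sum of squares below 1e-12 is floored (noiseless fixtures).
* BH adjustment delegates to `statsmodels.stats.multitest` and is verified
  against an independent step-up implementation; NaN (non-converged)
  entries never enter the family.
* Epoching has a vectorised fast path for uniform-grid tables and a
  per-trial fallback for ragged ones; both are tested for agreement.
* Trials shorter than 2500 ms post-onset get invalid tails, not errors;
  a condition absent at a sample flags that contrast undefined, not fatal.

## Known limitations

* The original studies' exact random-effects specification and estimator
  are not published; cluster windows on real data should be expected to
  match approximately (window overlap), not bit-exactly.
* The free-gaze design's keypress behaviour is simulated as a fixed
  per-trial accuracy, not a decision model.
* No ROC/AUC analysis with an innocent group (out of scope, as in the
  source paradigm), and no multivariate fusion of measures.
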