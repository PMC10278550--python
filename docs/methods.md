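# Methods

## The pipeline in one paragraph

A copy-task recording is a 1000-Hz stream of gaze position (pixels) and
pupil size (recorder arbitrary units, a.u.) plus a trial table giving each
trial's delay condition, experiment and correctness. The pipeline
(1) partitions the stream into left/right screen visits with a hysteresis
rule, (2) promotes left visits that survive the trial's delay into
*sampling events* with a model onset, dwell and build duration,
(3) extracts per-event pupil metrics from onset-locked epochs, and
(4) fits linear mixed-effects models (LMEs) relating those metrics to
build duration (encoding depth) and, in the continuous-report variant, to
angular response error (encoding precision).

## Event definition and time accounting

All intervals are half-open `[enter, leave)` in integer milliseconds.
Gaze is binarized at the screen midline; a sample exactly on the midline
is *right* (deterministic half-open convention). An excursion to the
opposite half shorter than the hysteresis threshold (default 100 ms) does
not end the current visit; blink samples inherit the current side so a
blink can never split an event.

A left visit whose overlap with a trial covers at least the trial's delay
produces a sampling event with model onset at `visit start + delay`.
Shorter left visits are aborted samples: no onset, no event, and the delay
timer does not carry over to the next visit. Dwell runs from the model
onset (default; configurable to visit start via `dwell_reference` — the
verbal definition of "time until gaze shifted back" leaves the anchor
open, and the encoding-relevant reading anchors at onset) to the start of
the first sustained (≥ hysteresis) right period, truncated at trial end.
Build runs from dwell end to the first sustained left return or trial end,
with the terminator recorded in `ended_by`.

Trial-level filters drop events from trials with any misplaced item and
events outside the medium (1500 ms) / long (3000 ms) delay conditions; the
200-ms condition's dwells are too short for stable pupil estimates. Drop
reasons are tallied, never silent.

## Pupil features

* **Blink handling.** Invalid runs (pupil 0 / recorder blink flags) are
  widened by 50 ms on each side — the measured trace is deformed around a
  blink, not only inside it — and linearly interpolated between the valid
  neighbours. Runs touching a recording edge stay invalid. Interpolated
  samples are flagged `reconstructed`: usable for medians, but they do not
  count toward the per-window validity quota.
* **Baseline**: median pupil size over `[-100, 0)` ms before model onset.
* **Orienting amplitude**: after subtractive baseline correction, the
  median over `[500, 1000]` ms (closed window), sign-flipped so positive =
  stronger constriction. The signed median is retained alongside. Storing
  the magnitude makes regression coefficients read "stronger orienting →
  longer build"; the sign convention is a genuine free choice and flips
  the sign of the pupil coefficients, nothing else.
* **Control metric**: max over `[0, 300]` minus min over `[500, 1000]` ms,
  insensitive to the small pre-constriction dilation.
* **Validity quota**: a metric is absent when fewer than 50% of a window's
  samples were actually measured. The threshold guards against medians
  over nearly-empty windows; at 1000 Hz its exact value is not critical.
* **Window endpoints.** Baseline half-open, orienting closed. At 1000 Hz
  the inclusivity of a single endpoint sample is scientifically
  immaterial but must be pinned down for bit-exact tests; these are the
  package's fixed choices.
* **Gaze filter**: an event is analysable only if every valid gaze sample
  in `[onset, onset + 1000)` ms lies within the model-grid ROI expanded by
  2° of visual angle (closed boundary). This is the strict *continuous*
  reading of "looked at the grid for at least 1000 ms"; a cumulative
  variant (total in-ROI time ≥ 1000 ms, interruptions allowed) is
  available via `inclusion_continuous=False`. Whether the margin is
  measured from the ROI edge (implemented) or centre is equally
  unspecified in verbal task descriptions; edge distance is the weaker,
  safer assumption.
* **Robust z** (for visualisation only): per participant, subtract the
  median and divide by the *unscaled* median absolute deviation (no
  1.4826 factor). Predictors enter the models on their raw scales.

## Mixed models

All models use participant-level random intercepts plus random slopes for
the delay condition (or the set size × prototypicality design in the
precision analyses), fit with statsmodels `MixedLM`. REML is used for
reported coefficients; ML when AICs are compared across fixed-effect
structures (AIC = −2·llf + 2·k with k counting fixed effects and
covariance parameters; ties go to the smaller model, independent of
candidate order). Significance is the normal approximation |t| > 1.96
with no degrees-of-freedom correction — a deliberate, documented
divergence from Satterthwaite-style corrections. Condition is a
categorical factor with *medium* as reference; experiment categorical
with Experiment 1 as reference. Durations enter in seconds, pupil in a.u.
Non-converged fits are retried with alternative optimizers on the *same*
model and flagged; the random structure is never simplified silently.

The 10-ms time-course model (`pupil ~ precision group × set size ×
prototypicality` per bin) reports uncorrected per-bin significance and
contiguous significant runs. Bins whose outcome is an exact linear
function of the design — the noise-free synthetic limit, where the
likelihood degenerates — are solved by exact least squares with the
convention t = ±∞ for nonzero coefficients and t = 0 for structural
zeros, keeping the significance flags a pure function of (β, se,
threshold). Bins with fewer than two precision groups are skipped and
logged. A cluster-based correction is out of scope; runs are reported as
observed.

## The synthetic generators

The copy-task generator emulates: two-screen gaze alternation with
instantaneous saccades and jittered fixations (segmentation only depends
on half-crossings and hysteresis, so saccade kinematics add nothing);
delay holds followed by model onset; an event-locked constriction kernel
(raised-cosine dip, onset 250 ms, trough 650 ms, recovery 1000 ms —
only the timing and amplitude matter for median-window features); tonic
per-event baselines around a per-participant mean (giving the
within-participant variance the trial-level LME needs); white pupil
noise; Poisson blinks (pupil 0, invalid); sub-100-ms gaze flickers to
exercise the hysteresis rule; aborted visits; and planted gaze-filter
violations. Build duration follows the planted linear model

```
build = b0 + b1·baseline + b2·|amplitude| + b3·dwell + condition + u_p + e
```

floored at 0.1 s (durations are physical). Defaults are the study
conditions: 24 participants split half/half across two experiments, 35
trials per delay condition (200/1500/3000 ms), b1 = 0.0009 s/a.u.,
b2 = 0.003 (Exp 1) / 0.0001 (Exp 2) s/a.u., b3 = 0.10 (Exp 1) / 0.19
(Exp 2) s/s, +0.33 s on build and +1.64 s on dwell in the long condition,
and a +1312.68 a.u. baseline offset in Experiment 2 (darker stimuli).
Event counts per trial and dwell spreads are free parameters with
plausible defaults (2–4 events/trial; dwell ~ N(1.0, 0.5) s), as no
distributional ground truth exists for them.

Two deliberate consequences of the planted structure: the *marginal*
condition contrast on build (~0.5 s) exceeds the direct plant (0.33 s)
because part of the condition effect is mediated by dwell; and the
*measured* orienting amplitude is a fixed fraction (≈0.749) of the
planted kernel amplitude — the median of the unit kernel over the
500–1000 ms window — so full-pipeline slopes on measured amplitudes scale
accordingly. Recovery studies therefore either use the event-level fast
generator (`simulate_copy_events`), where the plant is defined on the
quantities the models consume, or compare against the planted event
table directly.

The continuous-report generator draws set size (1–4), prototypicality,
per-trial baseline and constriction amplitude, and plants

```
error = a0 + 5.78·set size + 0.002·baseline − 0.004·|amplitude| + u_p + e
```

truncated to [0, 180]°. The intercept (15°) and residual sd (9°) keep the
truncation mass below ~0.5% so planted slopes survive the clip; these are
typical continuous-report error scales. The orienting coefficient is
negative under the magnitude coding so that stronger constrictions plant
*smaller* errors. An optional group-effect offset, confined to a half-open
post-onset window (default `[500, 1000)` ms), plants the time-course
separation used by the run-recovery checks. Per-trial traces are
baseline + kernel + noise on a 1-ms grid.

What the generators do **not** emulate: saccade kinematics and
microsaccades, pupil foreshortening with gaze angle, luminance-driven
pupil responses of actual stimuli, slow tonic drifts within a recording,
or correlated blink/attention dynamics. Passing tests therefore establish
correctness of the *pipeline mechanics and estimators* under the stated
generative model, not robustness to every artifact of real recordings.

## Problem sizes used in the checks

Segmentation oracle equivalence runs at 1 participant × 10 trials per
condition, noiseless. The hysteresis and feature-exactness properties use
1000 random fixtures/epochs each. Parameter recovery runs 100 replicate
studies at the design size (24 × 35 × 2 conditions, event level) and
checks that each planted coefficient lies in its 95% Wald CI in ≥ 90; the
type-I calibration runs 200 replicates with orienting and dwell effects
planted at zero and requires the |t| > 1.96 rate within 5% ± 2 binomial
s.e. (these are within-participant terms, where the normal approximation
is well calibrated; between-participant terms at 24 clusters are known to
be slightly anticonservative without df correction). The precision slope
check uses one study at 20 × 360 trials; the time-course run check uses
8 × 100 trials, noiseless, 120 bins.

## Known limitations

* The ASC reader covers only numeric sample lines and SBLINK/EBLINK
  markers — a deliberate subset, not an EDF/ASC parser.
* statsmodels `MixedLM` occasionally reports non-convergence for the
  full random structure of the precision model; estimates remain usable
  and the flag is surfaced in `FitResult.converged`.
* `validate_build_proxy` implements the placement/build correlation
  operation; the external dataset it was designed for is not bundled, so
  it is exercised on synthetic fixtures only.
* Monocular data only; no gaze calibration or pupil mm conversion (the
  analyses are unit-free in a.u. by design).
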