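# Methods

This note documents the model assumptions, parameter defaults, numerical
choices and known limitations of the `capressor` pipeline.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model

The aortic pressure during post-resuscitation recovery is modeled as an
additive superposition

```
P(t) = baseline + pulse(t) + drift(t) + vent(t) + Σ_j A_j / (1 + exp(−k_j (t − t0_j))) + ε(t)
```

* `pulse(t)` — the beat train.  The default morphology is asymmetric: a
  raised-sine systolic upstroke over the first 30 % of the cycle followed
  by an exponential diastolic decay (time constant 0.25 cycles) rescaled to
  close the cycle continuously.  A pure-sinusoid mode is retained for
  analytic checks.  The waveform is scaled so the per-beat maximum minus
  minimum equals the configured pulse pressure and the per-beat mean equals
  the configured baseline MAP.
* `drift(t)` — linear (`slope · t`) or saturating-exponential baseline
  drift, representing post-resuscitation instability (recovery or
  decompensation).
* `vent(t)` — a sinusoidal ventilation artifact.
* each bolus contributes a logistic (sigmoid) step of amplitude `A`
  (mmHg, may be ≤ 0), rate `k` (1/s) and midpoint `t0`; the annotation time
  of the bolus always precedes `t0`.
* `ε(t)` — white Gaussian measurement noise.  No colored-noise model is
  included; the artifact spectrum of the source acquisition chain is
  unknown, and white noise plus the deterministic ventilation sinusoid is
  the simplest structure that stresses every pipeline stage.

Right-atrial and intracranial channels are low-amplitude scaled copies of
the same beat clock plus noise — sufficient to exercise the perfusion-
pressure computations, with no independent physiology (no venous return or
intracranial compliance model).  Superposition is exact by construction, so
ground truth is known for every generated quantity.

### Generator defaults (study conditions)

| parameter | default | rationale |
| --- | --- | --- |
| sampling rate | 1000 Hz | acquisition rate of the modeled recordings |
| heart rate | 90 bpm | mildly tachycardic post-resuscitation swine rhythm |
| baseline MAP | 45 mmHg | hypotensive recovery state |
| pulse pressure | 25 mmHg | systolic near the 60 mmHg circulation threshold |
| ventilation artifact | 0.25 Hz, 3 mmHg | ventilator-rate oscillation the smoothing must suppress |
| noise SD | 1.5 mmHg | visible beat-to-beat jitter without obscuring morphology |
| logistic rate k | 0.2–0.5 1/s | response developing over tens of seconds |

The scenario battery (`clean_responder`, `declining_responder`,
`non_responder`, `rapid_decompensation`) fixes the bolus annotation at 85 s
and the true midpoint at 90 s of a 180 s recording; the decompensation case
uses a −0.20 mmHg/s drift so the drift loss across the ±40 s comparison
window (−15 mmHg) exceeds the 5 mmHg bolus benefit, producing a genuinely
negative before/after delta.

## Beat detection

Detection runs on a 0.5–5 Hz band-passed copy (2nd-order Butterworth,
zero-phase) of the aortic channel, so baseline drift and the ventilation
artifact cannot move beat boundaries; summaries always use raw samples.
Systolic peaks are prominence-filtered local maxima separated by at least
250 ms; beat boundaries sit at the pre-upstroke trough between peaks.
Beats shorter than 250 ms or longer than 2 s (outside plausible bounds for
a ~30 kg swine) are excluded.  A signal whose robust excursion (2nd–98th
percentile of the band-passed copy) is below 5 mmHg is treated as
pulseless: an empty beat list plus a warning, not an error.  All bounds are
configurable (`BeatDetectionOptions`).

MAP is the within-beat sample mean — not the `(2·AoD + AoS)/3` cuff
approximation — because the full waveform is available.

## Perfusion pressures

The field-standard resuscitation conventions are used: CPP = AoD minus the
right-atrial pressure at the aortic diastolic instant; CePP = MAP minus the
mean intracranial pressure over the beat.  When either reference channel is
absent the perfusion series is empty and midpoint detection falls back to
the systolic pressure alone.

## Bolus isolation

Every annotated injection (calcium, epinephrine, bicarbonate) delimits
segments; a calcium bolus owns the interval from half-way to the previous
injection to half-way to the next (recording edges otherwise).  Segments
with less than 40 s of context on either side are kept but marked unusable,
so bolus counts remain auditable while only well-isolated responses enter
the statistics.  Consecutive calcium boluses closer than 80 s therefore
produce two unusable segments, never a merged one.

## Midpoint detection

The response midpoint is the inflection of the sigmoid, located where the
second derivative of the pressure trend crosses zero.  Differentiating a
beat-level series twice is numerically hostile: the ventilation artifact
(3 mmHg at 0.25 Hz by default) carries second-derivative amplitude of
order 1 mmHg/s², an order of magnitude above the sigmoid's own curvature
(`0.096 · A · k²` ≈ 0.03–0.3 mmHg/s² over the amplitudes and rates of
interest).  A plain 15-beat windowed average leaves ≈ 13 % of the artifact
(its rectangular-window stop band falls off slowly), which still swamps the
signal.  Detection therefore:

1. resamples each beat-level signal (AoS, and CPP/CePP when present) onto a
   uniform 0.5 s grid by linear interpolation;
2. applies a zero-phase 4th-order Butterworth low-pass whose cutoff is one
   cycle per two detection windows — 0.05 Hz for the default 15-beat window
   at 90 bpm.  At 0.05 Hz the 0.25 Hz artifact is attenuated by ~5⁴ in
   amplitude while the logistic transition (spectral content below
   ~k/2π ≈ 0.03–0.08 Hz) passes; being zero-phase, the filter leaves the
   inflection time unmoved;
3. takes central finite differences twice, discards one cutoff period at
   each end of the segment (filter settling fabricates curvature there),
   and lists zero-crossings after the bolus annotation whose second-
   derivative swing exceeds ε = 0.01 mmHg/s² on both sides;
4. keeps, per signal, the crossing with the largest total swing (the
   dominant curvature change), and takes the median across signals as the
   consensus midpoint.

Validity requires, when two or more signals are available, that at least
two of them produce crossings agreeing within 5 s.  Without this rule about
a third of pure-noise segments yield a spurious "response" from a single
signal's noise floor; with it, an annotated bolus with no physiological
effect is reported as `valid=False` (a value, not an exception) and
classified as no-effect.  The 15-sample windowed average remains the
display smoothing for exported tables and figures; only the detection path
uses the sharper filter.  Window widths, cutoff coupling, ε, the resampling
step and the agreement tolerance are all exposed in `SmoothingConfig`.

Measured on the generator's study conditions (amplitudes 5/10/15 mmHg,
rates 0.2/0.5 1/s, 2 mmHg noise), the recovery study
(`capressor.recovery.midpoint_recovery_study`, also run by the acceptance
script) finds the midpoint with a median error of ≈ 0.15 s, ≈ 98 % of
segments within 3 s.

## Normalization

Normalized time is beat time minus the consensus midpoint; each pressure
has its value at the beat nearest t = 0 subtracted.  Anchoring on an actual
beat (not an interpolated value) keeps the "zero at the midpoint" invariant
exact to machine precision, which the across-segment band construction
relies on: each segment's interpolant includes the (0, 0) knot that defines
the normalized frame, so the band's mean and SD at t = 0 are exactly zero
with any segment set.  Normalization is idempotent and invariant to adding
a constant to all pressures.

## Before/after comparison and classification

Windows default to the open intervals (−40, −36) s and (36, 40) s of
normalized time; means are arithmetic over beats strictly inside the
window, and a segment with an empty window is dropped from the paired test
with a warning.  Deltas are tested with a two-sided paired *t*
(`scipy.stats.ttest_rel`; zero-variance differences are flagged degenerate
rather than silently producing NaN) and their normality with Shapiro–Wilk.
No multiple-testing correction is applied across MAP/AoS/AoD and repeated
boluses within an animal are treated as independent — the analysis mirrors
the design it re-implements rather than improving on it.

Classification: boluses without a detectable sigmoid (invalid midpoint, or
no analyzable delta) are `no_effect`; detectable responses split into
`responder` (ΔMAP > 0) and `negative_delta` (ΔMAP ≤ 0).  The two notions
are deliberately distinct: a bolus can manifest a clear sigmoid response
and still show a negative before/after delta when the animal is
decompensating faster than the bolus helps.

## Blood chemistry

The packaged fixture (`capressor/data/blood_chemistry.csv`) transcribes the
per-animal arterial pH and ionized-calcium panels of three swine cohorts
from the source publication's printed tables, with a provenance header.
Rounds an animal did not survive to have no row; a literal `missing` marks
rounds whose blood-gas data were lost; `suspect=1` marks cells whose
printed values are ambiguous or physiologically implausible (e.g. an iCa of
1.72 mmol/L amid neighbors of 1.2–1.3) — they are transcribed verbatim,
never corrected, and the concatenated print of the cohort-3 table is
ambiguous enough that its calcium-bolus counts (41 under this parse) do not
reconcile with the 37 boluses the source reports; cohort-3 cells are
therefore never used as exact test targets.

Groups are baseline / round 1 / "other rounds" (round ≥ 2).  For the other-
rounds group two poolings exist: `per_animal` (each animal contributes the
average of its round-2+ values; the default, matching the source's
"average remaining rounds" aggregation) and `pooled` (every record
individually).  Per-animal averaging reproduces every published summary
cell at 2-dp rounding (iCa 1.19 ± 0.12, pH 7.34 ± 0.08, ANOVA p = 0.031);
pooling does not (iCa 1.21 ± 0.13, p = 0.055), and `table3_report` flags
that disagreement explicitly instead of matching silently.  Sample (n−1)
standard deviations are used throughout; a single-record group reports its
value with an undefined (NaN) SD.

## Recovery studies

`capressor.recovery` packages the three simulation studies the acceptance
script runs: midpoint recovery (above); effect-size recovery — fifty
37-bolus cohorts with amplitudes drawn from N(12, 6²) mmHg, where the
group mean of measured MAP deltas tracks the injected mean within
≈ 1 mmHg (undetected near-zero-amplitude boluses are excluded by the
pipeline, a small conservative selection the study quantifies rather than
hides); and paired-*t* type-I calibration (n = 34 null differences, 2000
replicates, rejection rate ≈ 0.05).  Problem sizes were chosen so the full
suite and the acceptance script each run in a few minutes on one CPU.

## What passing tests do and do not show

The synthetic generator shares the pipeline's additive-superposition
worldview: responses are exactly logistic, noise is white, the ventilation
artifact is a pure sinusoid, and beats are strictly periodic in phase.
Passing recovery tests therefore demonstrate internal correctness — the
pipeline finds what the generator injected under realistic amplitudes,
rates, drift and artifact levels — not field performance on real
recordings, where responses deviate from sigmoids, artifacts are
non-stationary, and catheter events can masquerade as curvature changes.
The chemistry module, by contrast, is validated against the actual
published tables.

## Known limitations

* Pressure-only beat detection; no ECG R-wave gating, no arrhythmia
  handling.
* Midpoint detection assumes one dominant curvature change per segment;
  overlapping drug effects are out of scope (segmentation isolates, it does
  not deconvolve).
* No pharmacokinetic or closed-loop cardiovascular modeling; no sigmoid
  curve fitting (the midpoint is approximated from curvature, matching the
  analysis this package re-implements).
* The cohort-3 chemistry transcription carries irreducible print
  ambiguities, flagged per cell.
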