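# capressor

Beat-by-beat analysis of the arterial pressor response to intravenous
calcium boluses given during post-resuscitation hypotension.

## The problem

After resuscitation from profound hypoxic shock (pseudo-pulseless
electrical activity), animals and patients are often hypotensive and
refractory to catecholamine pressors, and serum ionized calcium (iCa) is
frequently depressed.  When calcium is given ad hoc as intravenous boluses,
the blood-pressure response is superimposed on unstable, drifting baseline
hemodynamics, so the size of the pressor effect cannot be read off the raw
tracing.  `capressor` implements a reusable pipeline for exactly this
analysis:

1. **Beat extraction** — individual heartbeats are identified on a
   band-limited (0.5–5 Hz) copy of the 1 kHz aortic pressure waveform;
   per beat, MAP (within-beat mean), AoS (systolic maximum) and AoD
   (diastolic minimum) are computed from the raw samples, along with
   coronary (CPP = AoD − right-atrial pressure at diastole) and cerebral
   (CePP = MAP − mean intracranial pressure) perfusion pressures.
2. **Bolus isolation** — each calcium bolus owns the interval reaching
   half-way to the neighboring injection of any drug (calcium, epinephrine,
   bicarbonate), and is usable for statistics only with ≥ 40 s of context
   on both sides.
3. **Midpoint normalization** — the pressor response is approximately
   logistic in time, `A / (1 + exp(−k (t − t₀)))`.  Its midpoint t₀ (the
   inflection) is located per signal (AoS, CPP, CePP) as the dominant
   zero-crossing of the second derivative of the smoothed beat series, and
   the consensus is the median across signals.  Each segment is then
   re-expressed with the midpoint at the origin: t → t − t₀ and each
   pressure minus its value at the beat nearest t₀, so every response
   passes through (0, 0).
4. **Before/after comparison** — normalized pressures are averaged over
   −40 < t < −36 s and 36 < t < 40 s; per-bolus deltas (after − before) are
   tested with a two-sided paired *t* test, normality checked by
   Shapiro–Wilk, and boluses classified as responder / negative-delta /
   no-effect.
5. **Blood chemistry** — longitudinal pH and iCa panels are aggregated
   across experimental rounds (baseline / round 1 / later rounds) and
   compared by one-way ANOVA.

Because the original raw recordings are not publicly deposited, the package
ships a ground-truthed synthetic waveform generator (pulsatile beat train,
ventilation artifact, baseline drift, injected logistic responses, white
noise) so every stage is testable against known truth.

## Worked example

```python
from capressor import Drug, DrugEvent, PressorResponseModel
from capressor.synthetic import scenario_params, generate_recording

params = scenario_params("clean_responder", seed=1)   # 12 mmHg bolus at t0 = 90 s
recording, truth = generate_recording(params)
events = [DrugEvent(b.annotation_time_s, Drug.CALCIUM, "10 mg") for b in truth]

results = PressorResponseModel(recording, events).fit()
print(results.summary())
```

```
Calcium pressor-response analysis
=================================================
boluses: 1   usable: 1   analyzed: 1
classification: 1 responder, 0 negative-delta, 0 no-effect
-------------------------------------------------
pressure   delta (mmHg)        t          p
     MAP    12.0
     AoS    11.8
     AoD    11.4
=================================================
```

The injected 12 mmHg amplitude is recovered as the measured MAP delta, and
the detected midpoint (`results.midpoints[0].midpoint_time_s` = 89.89 s)
sits within a tenth of a second of the true inflection at 90 s.  With
several analyzed segments the group statistics appear too — on an 8-bolus
synthetic cohort with amplitudes drawn from N(12, 6²):

```
delta MAP = 9.9 +/- 2.8 mmHg, t = 9.80, df = 7, p = 2.4e-05
counts: {'responder': 8, 'negative_delta': 0, 'no_effect': 0}
```

The same pipeline runs from the shell:

```sh
capressor simulate --scenario clean_responder --seed 1 --out sim/
capressor analyze --recording sim/clean_responder.csv \
                  --events sim/clean_responder_events.csv --out run/
capressor chemistry --out chem/
```

`analyze` writes a segment manifest, per-bolus normalized tables, a summary
JSON, the mean ± SD band of normalized pressures and the delta-MAP
histogram.  `chemistry` aggregates the packaged cohort blood-gas tables and
prints the iCa ANOVA (`F=3.701, p=0.0309` across baseline / round 1 / later
rounds).

## Layout

| module | role |
| --- | --- |
| `capressor.synthetic` | ground-truthed surrogate recordings and scenario battery |
| `capressor.io` | delimited-text recordings, drug events, pipeline outputs |
| `capressor.beats` | beat detection and per-beat MAP/AoS/AoD, CPP/CePP |
| `capressor.segmentation` | per-bolus isolation boundaries |
| `capressor.midpoint` | smoothing, second derivative, midpoint detection, normalization |
| `capressor.stats` | windowed comparison, paired *t*, Shapiro–Wilk, classification, band, histogram |
| `capressor.chemistry` | blood-gas fixture, aggregation, one-way ANOVA |
| `capressor.model` | `PressorResponseModel` / `PressorResponseResults` orchestration |
| `capressor.recovery` | parameter-recovery studies on synthetic data |
| `capressor.cli` | `simulate` / `analyze` / `chemistry` / `report` subcommands |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical design choices.
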