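# sleeptap

Behavioral sleep measures from passively sensed smartphone interactions, and
their longitudinal associations with self-reported sleep disturbance,
depression and anxiety.

## The problem

People interact with their phones around the clock, and the *absence* of
interaction at night is a usable behavioral trace of sleep. For patients in
virtual mental-health care, this trace is collected anyway, costs nothing to
acquire, and — unlike actigraphy — directly certifies wakefulness whenever
the phone is touched during the night. `sleeptap` implements an end-to-end
analysis for this kind of data:

1. **Binning.** Timestamped interaction events (taps, scrolls, typing, app
   changes, screen-on) are aggregated into 96 binary 15-minute bins per
   calendar day. A day is *adequate* if activity spans ≥ 4 distinct clock
   hours; a patient is retained with ≥ 28 adequate days.
2. **Inferred sleep period (ISP).** The longest daily run of inactive bins
   (00:00–23:59, non-circular).
3. **Expected sleep period (ESP).** Per non-overlapping 30-day window
   (valid with ≥ 15 adequate days), each bin's activity fraction over
   adequate days is binarized by exact 1-D two-means clustering; the ESP is
   the longest *circular* run of inactive bins, so a habitual sleep window
   spanning midnight is one run.
4. **Overlap percentage** — the fraction of a day's ISP bins inside the ESP,
   a duration-naive regularity measure — and **disruptions**, the count of
   active bins inside the ESP (nocturnal wakefulness).
5. **Surveys.** DSM-5 Level-1 style items (0–4 Likert) are scored into
   sleep-disturbance, depression and anxiety domain means; each survey is
   linked to the mean of the behavioral measures over the 14 days before it
   (≥ 3 viable days required).

## The model

Each predictor is split into a between-person component (the person mean,
`bp.x`) and within-person deviations (`wp.x`), and each outcome is fit with
a two-level linear mixed model (REML):

```
y_it  = β0i + β1i·wp.Overlap_it + β2i·wp.Disruption_it + β3i·wp.Duration_it + e_it
β0i   = γ00 + γ01·bp.Overlap_i + γ02·bp.Disruption_i + γ03·bp.Duration_i
            + γ04·Age_i + γ05·Gender_i + γ06..08·Diagnosis_i + γ09·Location_i + u0i
βki   = γk0 + uki                                   (k = 1, 2, 3)
```

with independent zero-mean normal random effects `u0..u3` and residual `e`.
Before fitting, observations whose Cook's distance (from a pooled
least-squares regression on the six behavioral predictors) exceeds 4× the
mean are removed, and a two-sample Kolmogorov–Smirnov test verifies the
cleaning left the variable distributions intact. An ID-level bootstrap
(resampling 20% of patients with replacement, keeping each patient's full
series) reports per-coefficient detection power.

A bundled synthetic-cohort generator produces event streams, surveys and
demographics from known parameters — outcomes are generated from the *same*
pipeline-computed predictors the model later sees, so parameter recovery is
testable end to end.

## Worked example

```python
from sleeptap import GeneratorConfig, simulate_cohort

cohort = simulate_cohort(GeneratorConfig(n_patients=40, days_per_patient=120, seed=7))
viable = cohort.measures[cohort.measures["viable"]]
print(viable[["overlap", "disruptions", "esp_duration_h"]].mean())
```

(equivalently `python examples/01_simulate_cohort.py`) prints:

```
mean overlap:        0.90   # fraction of the daily ISP inside the habitual ESP
mean disruptions:    5.42   # active 15-min bins inside the ESP per night
mean ESP duration:   7.79 h # habitual nightly inactivity window
```

Fitting the sleep-disturbance model on a 120-patient cohort
(`examples/03_mixed_model_fit.py`) removes 4.58% of observations by the
Cook's-distance rule and recovers the generating coefficients within
sampling error, e.g. `wp_disruption ≈ 0.069 (SE 0.062)` against a generating
value of 0.045 and `bp_overlap ≈ -1.77 (SE 1.20)` against -0.90, with all
KS p-values ≥ 0.999 after cleaning. `examples/` contains one short script
per capability (simulation, daily measures, model fit, bootstrap power,
weekday/weekend contrast); each prints what it computes and what the
numbers mean.

A thin CLI mirrors the pipeline stages for file-based use:

```
sleeptap simulate --n-patients 50 --days 120 --seed 1 --out work/
sleeptap measures --events work/events.csv --out work/
sleeptap aggregate --measures work/daily_measures.csv --surveys work/surveys.csv \
    --demographics work/demographics.csv --out work/observations.csv
sleeptap fit --observations work/observations.csv --outcome sleep --out work/fit.json
sleeptap bootstrap --observations work/observations.csv --out work/power.csv
```

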