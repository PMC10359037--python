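# Methods

This note documents the models, procedures and numerical choices behind
`sleeptap`, and what the synthetic-data experiments do and do not establish.

## Behavioral sleep measures

**Binning.** An event belongs to 15-minute bin `k ∈ {0..95}` of a calendar
day iff its timestamp falls in `[15k, 15(k+1))` minutes after local
midnight (half-open intervals; the day boundary is the local clock's
midnight, with no timezone inference or DST handling — duplicate clock
labels would simply OR together). Calendar days with no events inside a
patient's first-to-last-event span are emitted as all-inactive rows; they
fail the 4-distinct-hours adequacy rule and are filtered downstream rather
than silently dropped. The 28-adequate-day patient filter counts *any* 28
days, not consecutive ones — the consecutiveness is deliberately not
assumed.

**Inferred sleep period (ISP).** The longest maximal run of inactive bins in
the day, scanned 00:00→23:59. Ties are broken by the earliest start (any
deterministic rule works; earliest is the simplest). The scan is
non-circular by construction, so a true sleep interval that crosses midnight
is truncated at the boundary. This bias is inherent to the daily measure and
is *not* corrected: the habitual (ESP) measure, which is circular, is the
anchor for the regularity and disruption measures.

**Expected sleep period (ESP).** Windows of 30 consecutive days are anchored
at each patient's first observed day, non-overlapping; a window is valid
with ≥ 15 adequate days, and trailing windows shorter than 30 days are
invalid (the half-of-days rule has no meaningful rescaling for short
windows). Bin `k`'s activity fraction is the share of the window's adequate
days with bin `k` active — inadequate days are excluded from the denominator
because they carry no usable signal. The fraction profile is binarized by
two-means clustering and the ESP is the longest circular run of inactive
bins, with ties broken by the run starting earliest after the longest active
run.

**Two-means binarization.** For two clusters on scalar data the k-means
objective is minimized by a threshold in sorted order, so the global optimum
is computed exactly: prefix sums give each of the 95 sorted-order splits'
within-cluster sum of squares in O(n), ties are broken toward the smaller
low cluster, and the lower-mean cluster maps to inactive. An iterative Lloyd
refinement was considered and rejected: on profiles without clear bimodal
structure Lloyd from extreme seeds can stall in local optima, whereas the
exact scan is deterministic and provably optimal (the test suite checks it
against a brute-force oracle on 1,000 random profiles, including tied and
bimodal ones). A window whose 96 fractions are all identical has no
derivable ESP and is marked invalid.

**Overlap and disruptions.** Overlap is `|bins(ISP) ∩ bins(ESP)| /
|bins(ISP)|`, bin sets taken modulo 96 — deliberately naive to duration, so
a short nap-like ISP fully inside the ESP scores 100%. Disruptions count the
day's active bins inside the ESP. Both exist only on *viable* days: adequate,
in a valid window, with an ISP present.

## Surveys and aggregation

Domain scores are item means on the 0–4 scale (sleep: 1 item; depression: 2;
anxiety: 3); a domain with any missing item is absent for that occasion while
complete domains survive. Each survey is linked to the mean of each measure
over viable days in the 14 calendar days ending the day *before* the survey:
the instrument asks about the past two weeks, and same-day behavior postdates
part of that recall window (the upstream data source is silent on this; the
exclusive convention is documented here as an interpretation). Occasions
with < 3 viable days are dropped. Between-person components are person means
over *retained* occasions — matching exactly what a model fit on retained
rows can see — and within-person deviations therefore average to zero per
person by construction. Overlap always enters models as a 0–1 fraction; a
unit guard rejects percent-scale inputs, since a 0–4 outcome regressed on a
0–100 predictor would silently shrink every coefficient by 100×.

## The two-level model

Outcomes are modeled as continuous despite the bounded 0–4 scale, with fixed
effects for the six within/between behavioral terms plus person-level
demographics (age in uncentered years; indicators for male gender, three
primary diagnoses, rural location), a person random intercept, and
independent random slopes on the three within-person terms (variances only,
no covariances). Estimation is REML via statsmodels MixedLM; inference on
fixed effects is Wald-z with normal 95% CIs. Wald-z was chosen over
finite-sample df corrections (Satterthwaite/Kenward–Roger) for determinism
and portability; at the problem sizes used here (hundreds of patients) the
difference is negligible.

**Numerical conditioning.** Predictors are standardized internally before
fitting — raw scales span three orders of magnitude (overlap fractions vs
age in years), which can make the profiled GLS cross-product numerically
singular. Within-person columns are scaled but not centered (their means are
already ~0, and leaving them uncentered keeps the random-slope structure
exactly equivalent); person-level columns are centered and scaled. Estimates,
their full covariance, and slope-variance components are transformed back to
the raw scale exactly, so the reported model is the raw-scale model. The
likelihood is additionally guarded against evaluations exactly on the
zero-variance boundary (where the profiled solve is singular); interior
solutions are unaffected. If the optimizer still fails to converge, random
slopes are dropped one at a time from the zero boundary upward and the
dropped slopes are reported on the fit.

**Influence filtering.** Cook's distance is computed from a pooled
least-squares regression of the outcome on the six behavioral predictors
(per-observation Cook's distance is classically defined for fixed-effects
regression, and this mirrors an "initial regression" without demographics).
Observations with `D > 4 × mean(D)` are removed. The "four times" phrase is
ambiguous between baselines; 4× the mean D is the default and the classical
`4/n` cutoff is available via `baseline="4_over_n"`. On clean simulated
cohorts the mean-baseline rule removes ≈ 4–6% of observations. All-identical
inputs (every D equal) remove nothing; a genuinely rank-deficient design
raises an error naming the collinear columns.

**Confounder screening.** Each candidate demographic is tested one at a time
against each outcome in a random-intercept model (mixed rather than pooled,
since the occasions are nested); a variable missing in > 30% of observations
or constant is excluded before testing, and a variable is retained iff
p < 0.05 with at least one outcome. The union rule's type-I inclusion rate
for a null variable is therefore above 5% (up to ~14% across three
outcomes) — screening is a coarse gate, not a test.

**Bootstrap detection power.** Each replicate draws ⌈0.20·n⌉ patient IDs
with replacement; a patient drawn twice is relabeled as two distinct
patients so the grouping structure stays valid. Power is the share of
replicates where a coefficient is significant at 0.05 *with the same sign*
as the full-data estimate — sign-flipped significance is not credited.
Replicates whose fit fails are excluded from the denominator; demographics
that become constant inside a small resample are dropped from that
replicate's model (such a replicate cannot detect that coefficient). The
replicate count (500 by default) is configurable for desk-scale runs.

## The synthetic cohort generator

The generator emulates an adult virtual-behavioral-health cohort. Defaults
were fixed once, as study conditions, before any recovery experiments:

| parameter | default | rationale |
|---|---|---|
| sleep onset | 23.0 ± 1.0 h | typical adult onset; crosses midnight, stressing day-boundary handling |
| sleep duration | 8.4 ± 1.0 h | matches the habitual-window duration scale reported for such cohorts |
| onset jitter SD | person-specific, Gamma(shape 2), mean 1.0 h | regularity must *vary between people* for between-person overlap effects to be estimable |
| disruption rate | person-specific, Gamma(shape 4), mean 4.85 bins/night | nocturnal phone-check frequency at the reported cohort scale |
| daytime activity | 0.6 per waking bin | heavy but not saturated use |
| missing days | 5% | phones off / transmission gaps |
| surveys | every 30 days from day 44 | routine-care cadence; first survey after a full window plus recall period |
| fixed effects, variances | published sleep-disturbance column | see `sleeptap.config` |
| demographics | cohort marginal frequencies | age 56.7 ± 11.3, 25% male, 55% rural, diagnosis mix, ethnicity 34% missing |

Generation is two-phase: events first, then outcomes computed from the
*pipeline's own* measures (aggregated, decomposed into wp/bp exactly as at
fit time), plus per-domain person random effects and a normal residual,
clamped to [0, 4] and converted to item responses whose mean is the nearest
attainable domain mean (integers for the single sleep item, halves for
depression, thirds for anxiety). Two-phase generation makes the generating
and fitted models share predictors exactly, so fixed effects are recovered
without errors-in-predictor attenuation. The three domains share one
coefficient vector with independent random effects per domain; scheduled
surveys without ≥ 3 viable prior days are emitted flagged (outcome from the
intercept and random intercept only) and dropped by the pipeline.

Two distortions are built into the instrument and therefore into the
generator: clamping to [0, 4] and item-rounding. With an intercept near 2.5
and person-plus-residual SD near 1.3, roughly 10% of latent outcomes clamp,
attenuating recovered slopes by about that fraction and compressing the
random-intercept variance. This is a property of the bounded instrument, not
an estimation defect; the recovery experiments use a 2-standard-error
tolerance averaged over 20 replicates, which covers it.

**What the synthetic data does not emulate:** app-level content, typing
dynamics, employment-driven weekday structure (beyond an optional weekend
onset shift), seasonal variation, correlated measure/outcome noise, or the
real joint distribution of phenotypes. Passing tests establish that the
pipeline measures what it claims and that the estimation machinery recovers
known parameters under these conditions — not that the published cohort
estimates generalize.

## Problem sizes

The recovery study uses 20 replicates of 300 patients × 270 days × ~8
surveys (~2,400 observations per fit); structural invariants are checked on
10,000 random days (run-length oracle) and 1,000 random windows
(binarization oracle); calibration checks use 20 null fits of 70 × 5
observations and bootstrap runs of 30–50 replicates at 80 patients. These
sizes put every stage's bias well inside the tolerances checked while
keeping a full test run in the minutes range on one CPU.

## Known limitations

* The ISP truncates sleep at midnight; days where most sleep falls before
  00:00 yield short, morning-biased ISPs. The overlap measure inherits this.
* Overlap is duration-naive by design; a 15-minute ISP inside the ESP scores
  the same as an 8-hour one.
* The linear model ignores the outcome's discreteness and bounds; ordinal or
  beta regression variants are out of scope.
* No multiple-testing correction is applied across the three outcome models.
* Bootstrap power conditions on the full-data sign; for near-zero effects
  this halves the nominal null rate per tail.
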