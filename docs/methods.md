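# Methods

## Scope and data model

The package operates on epoch-level wrist-actigraphy recordings: ordered
non-negative activity counts at a fixed epoch length (default 60 s, which
must divide 3600 so epochs nest inside clock hours), with a parallel
validity mask marking off-wrist or missing epochs. One recording covers
one subject at one assessment wave (0, 8, 16 or 24 weeks in the supported
trial design). Timestamps are treated as local clock time with no
daylight-saving adjustment: the rhythms of interest are referenced to the
institutional daily schedule, not to UTC.

### Day alignment and missing data

Day-based statistics compare clock-time bins across days, so recordings
are first trimmed to whole calendar days: the series is clipped to start
at the first midnight at or after the recording start, and partial
leading/trailing days are discarded. A recording that began at 14:00 and
ran 7 days 5 hours therefore contributes 6 whole days.

Missing data policy, all config-exposed:

- a bin (hourly or finer) is invalid when fewer than 50% of its epochs
  are valid;
- a subject-wave is excluded from rhythm analysis when fewer than 3 whole
  days survive trimming;
- invalid bins are skipped inside the IS/IV sums, and IV successive
  differences are only taken between adjacent valid bins (pairwise
  deletion). No imputation is performed anywhere; gaps must arrive
  pre-masked as off-wrist epochs, and gapped timestamps are a structural
  error rather than something to repair silently.

## Non-parametric indicators

IS and IV are computed on hourly means (p = 24 bins/day), the convention
the indicator definitions are written in; the bin width is configurable
for sensitivity analyses. L5/M10 search the across-days average daily
profile with circular windows stepped at the profile's native resolution
(default: the epoch length), so a nocturnal L5 window spanning midnight
is always found; ties break to the earliest start time, making outputs
deterministic. RA = (M10−L5)/(M10+L5).

Degenerate inputs (constant series, M10+L5 = 0) raise typed errors rather
than returning arbitrary numbers. Useful calibration points: a perfectly
repeated non-constant day has IS = 1 exactly; i.i.d. noise has E[IS] ≈ 1/d
for d days and E[IV] ≈ 2; an hourly-sampled 24 h sine has IV ≈ 0.07. Note
that a *steep* anti-logistic rhythm (β ≈ 8) legitimately has hourly IV
around 0.12 — sharp rest/activity transitions contribute successive-
difference energy even without fragmentation.

## Anti-logistic extended cosinor

The model is the five-parameter sigmoidally transformed cosine

    f(t) = minimum + amplitude · expit(β · (cos(2π(t − φ)/24) − α))

— the standard anti-logistic member of the extended-cosinor family. The
equation is stated here prominently because published analyses often name
the model without printing it. Parameters and bounds used in fitting:

| parameter | meaning | bounds |
|---|---|---|
| minimum | curve floor (counts) | [0, max count] |
| amplitude | peak-to-floor span (counts) | (0, 2·max count] |
| φ (acrophase) | clock time of peak, decimal h | seed ± 12 h, reported mod 24 |
| α | trough/peak width | (−0.99, 0.99) |
| β | steepness of rise/fall | [0.1, 50] |

β is capped at 50 because square-wave-like fits otherwise diverge (the
likelihood is flat in β once the sigmoid saturates); α is kept strictly
inside (−1, 1) since |α| → 1 collapses the active or rest span to zero
width.

Fitting minimizes the sum of squared residuals over valid epochs at the
native epoch resolution, with time mapped to decimal hours since the
first midnight modulo 24, so the fitted phase is referenced to clock time
and invariant to the recording's start day. The objective is multi-modal
in phase, so a multi-start strategy is used: the closed-form 3-parameter
cosinor (linear least squares on cos/sin regressors) seeds minimum,
amplitude and acrophase, crossed with α ∈ {−0.6, 0, 0.6} × β ∈ {2, 8};
the best final SSE wins, ties going to the first start. If every start
fails, a fit flagged `converged=False` is returned with no fabricated
parameters.

Derived quantities: MESOR = minimum + amplitude/2; nadir time and level
located numerically on a 1-minute grid (the transform is monotone in the
cosine, so the nadir is antipodal to the acrophase); and the pseudo-F
statistic F = [(SSE₀ − SSE)/(k−1)] / [SSE/(n−k)] with k = 5, comparing
against the constant-mean null. The numerator degrees of freedom are
config-exposed because conventions differ; any fixed choice orders
subjects identically. Both the nadir *time* and *level* are emitted
because the literature is ambiguous about which one "nadir" denotes in
correlation tables; the pipeline's default nadir outcome is the time, and
this is switchable.

## Synthetic cohorts

The generator emulates the data structure of a cluster-randomized
bright-light trial in nursing-home dementia units:

- **Base rhythm**: per subject, anti-logistic parameters drawn once —
  acrophase ~ Normal(15.35, 1.66) decimal hours truncated into [0, 24)
  (a delayed, variable phase typical of severe dementia), amplitude
  U(40, 160) counts, minimum U(2, 20), α U(−0.6, 0.4), β U(1.5, 10).
- **Fragmentation**: an hourly two-state Markov gate (active/rest) that
  multiplies the smooth curve; rest attenuates activity to 10%. Defaults
  P(active→rest) = 0.15, P(rest→active) = 0.5 per hour reproduce frequent
  daytime naps and night awakenings and push IV upward with interpretable
  knobs.
- **Noise**: multiplicative gamma noise with mean 1 and coefficient of
  variation 0.6 (counts stay non-negative without truncation bias), plus
  an exponential additive floor (mean 1 count) so the night is never
  exactly zero. Counts are rounded to integers (disable with
  `quantize=False` for exact round-trip studies). The multiplicative and
  additive components jointly constitute the "noise scale": the additive
  floor is what erodes the day–night contrast (RA), while the
  multiplicative part mainly degrades IS.
- **Design**: 8 clusters with whole-cluster randomization, cluster sizes
  (8,8,8,7 | 8,8,7,7) giving 31 control + 30 intervention subjects at
  baseline; four waves at 0/8/16/24 weeks, 7-day recordings at 60 s
  epochs; per-wave dropout hazard 0.08 (monotone: a dropped subject never
  returns); a Normal(0, 0.3 h) cluster-level acrophase shift; covariates
  sampled to match the trial population (FAST stage 6 ≈ 75%, median age
  ≈ 84, 71% female, living-room exposure ≈ 3.1 h/day control vs 3.6 h/day
  intervention).
- **Injected effects**: a map (parameter, wave) → additive shift applied
  to intervention-arm generative parameters at that wave, e.g.
  ("acrophase", 16) → −1.0 advances the intervention acrophase one hour
  at week 16 only. With noise and dropout disabled this passes through
  exactly to the fitted group difference.

All randomness flows from a single `SeedSequence` (default seed
20170901), so identical seeds give bit-identical cohorts and file trees.

What the generator does *not* emulate: light exposure physics (exposure
enters only as the covariate minutes/day), seasonal or secular drift in
the rhythm, wave-to-wave within-subject parameter drift beyond the
injected effects, and non-random (informative) dropout. Passing tests on
this generator therefore demonstrate correctness and calibration of the
*analysis machinery* under the assumed data-generating process, not
clinical conclusions about real cohorts.

There is also an outcome-level simulator (`simulate_outcome_table`) that
draws directly from the mixed-model data-generating process (subject
random intercept + residual noise + optional injected arm-by-wave
shifts), used for calibration studies of the modelling stage — type-I
error and FDR over hundreds of replicate trials — where re-simulating
raw epochs per replicate would add cost but no information.

## Trial pipeline

Stages run in a fixed order: exposure exclusion → indicator computation →
phase filter → ln transforms → outlier rule → mixed models → BH
correction → baseline correlations. Each stage is also callable on its
own, and every exclusion is logged.

- **Exposure exclusion**: subjects averaging strictly less than
  30 min/day in the intervention area are removed entirely; exactly 30
  is retained. Missing exposure retains the subject with a warning by
  default (config: drop).
- **Phase filter**: observations with fitted acrophase earlier than the
  healthy-adult reference are removed together with the same subject's
  chronologically next observation, from the acrophase-family outcomes
  only (acrophase and, by default, nadir time). The reference default is
  12.983 decimal hours — the clock time 12:59 — because the source
  convention ("12:59" vs the decimal "12.59") is ambiguous; it is a
  config parameter.
- **Transforms**: amplitude, MESOR, pseudo-F and β are ln-transformed and
  renamed with an "(ln)" suffix; non-positive values are a hard error
  naming the subject and wave.
- **Outlier rule**: for the β model one extreme observation may need
  removal for estimability; operationalized as |robust z| > 5 using the
  median and normal-consistent MAD, applied to "beta (ln)" by default,
  logged per removal.
- **Models**: for each of the 12 outcomes (IS, IV, L5, M10, RA, and the
  seven cosinor quantities), a linear mixed model with fixed effects
  wave (categorical, baseline reference) + condition + wave×condition +
  baseline FAST (numeric), and a random intercept per subject, fitted by
  REML. The three interaction coefficients are the treatment-effect
  estimates, reported with Wald 95% CIs, p-values, n, ICC, and
  marginal/conditional variance explained (Nakagawa decomposition).
  With a single random intercept an "unstructured" covariance
  specification is vacuous, so random-intercept-only is the implemented
  model. Optional covariates (age, sex, comorbidity, medications) can be
  added but are off by default. Singular or non-convergent fits are
  returned flagged, never silently dropped.
- **Multiple testing**: Benjamini–Hochberg step-up with enforced
  monotonicity across the family of all 36 interaction tests (12 × 3);
  per-outcome families are a config option.
- **Correlations**: baseline Spearman correlations for all 35 cosinor ×
  non-parametric pairs, with two-sided p-values and star flags at 0.05
  and 0.0001; Spearman is rank-based, so computing it on untransformed
  values is equivalent to computing it after the ln transforms.

## Numerical and calibration notes

- The mixed-model Wald tests are asymptotic; at the design's size
  (~61 subjects, 4 waves) the empirical per-test type-I error measured
  over 200 replicate null trials is ≈ 0.049, and the probability of any
  BH discovery under the global null ≈ 0.055 — both consistent with
  nominal 5% to Monte-Carlo error.
- Problem sizes used in the shipped test suite and calibration runs:
  parameter-recovery studies use 100 subjects at 7 days (5-minute epochs
  for the noisy study); the injected-effect trial runs the full 61-subject
  cohort at 1-minute epochs; null calibration uses 200 outcome-level
  replicate trials with 4 outcomes × 3 waves each. These sizes give
  Monte-Carlo standard errors comfortably below the tolerances asserted.
- Integer rounding of simulated counts perturbs fitted parameters at the
  ~1% level for typical amplitudes; exact-recovery studies therefore use
  unquantized traces.
- L5/M10 window search uses a circular cumulative-sum; it is tested
  against an exhaustive double-loop search on hundreds of random
  profiles.

## Known limitations

- Sleep/wake scoring, raw accelerometry conversion, and proprietary
  binary device formats are out of scope; input is delimited epoch text
  (plain or device-export-with-preamble dialects).
- Acrophase is analysed on the linear scale, appropriate while the
  cohort's phases cluster far from the 0/24 h wrap; truly circular
  phase statistics are not implemented.
- The phase filter interacts with injected phase effects: removing
  phase-advanced observations is a selection on the outcome and can bias
  neighbouring-wave contrasts when an intervention genuinely advances
  phase. The filter is faithful to the protocol it implements; treat its
  output accordingly.
- Cluster is carried as a covariate and respected in randomization, but
  the default model (like the protocol it follows) has no cluster-level
  random effect; with 8 clusters a cluster variance component is barely
  estimable. The cluster-level acrophase shift in the generator is
  constant over waves and is therefore absorbed by subject intercepts.
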