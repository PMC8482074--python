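# rarlab

Rest–activity rhythm (RAR) analysis from wrist actigraphy, built for
longitudinal dementia-care trials: non-parametric circadian indicators,
anti-logistic extended cosinor fitting, a synthetic cohort generator, and
the full statistics of a cluster-randomized treatment trial.

## Who this is for

Researchers analysing epoch-level activity counts (e.g. 1-minute Actiwatch
exports) who need the standard circadian outcome set, and trialists who
need the downstream machinery — exclusion rules, mixed-effects
week-by-condition models, false-discovery correction — in one tested,
scriptable pipeline. Because real nursing-home actigraphy is rarely
shareable, the package includes a first-class simulator of fragmented,
phase-delayed cohorts so every stage can be exercised and calibrated
without any data download.

## The statistics at the core

**Non-parametric indicators**, computed on hourly means X̄ₕ of the n data
points Xᵢ (p per day), with overall mean X̄:

- Inter-daily stability  IS = n·Σₕ(X̄ₕ−X̄)² / (p·Σᵢ(Xᵢ−X̄)²) — 0 for noise,
  1 for a perfectly repeated day.
- Intra-daily variability  IV = n·Σᵢ(Xᵢ−Xᵢ₋₁)² / ((n−1)·Σᵢ(Xᵢ−X̄)²) —
  near 0 for a smooth 24 h sine, ≈ 2 for white noise.
- L5 / M10 — mean activity in the least active 5 h and most active 10 h
  circular windows of the average day, with their clock onsets.
- Relative amplitude  RA = (M10−L5)/(M10+L5).

**Anti-logistic extended cosinor** — a five-parameter sigmoidally
transformed cosine,

    f(t) = min + amp · σ( β · (cos(2π(t−φ)/24) − α) ),  σ(u) = eᵘ/(1+eᵘ)

with floor *min*, span *amp*, acrophase φ (decimal clock hours of peak),
trough/peak width α ∈ (−1,1), and steepness β > 0. Derived: MESOR =
min + amp/2, the nadir time/level, and a pseudo-F statistic against a
constant-mean null as a rhythm-robustness index. Fitting is multi-start
nonlinear least squares seeded by the closed-form 3-parameter cosinor.

**Trial pipeline** — per-outcome linear mixed models (REML, random
intercept per subject) with categorical wave × condition interactions and
baseline FAST (dementia staging) as covariate; exposure-based exclusion;
a phase filter relative to the healthy-adult acrophase reference (12.983
decimal hours); ln transforms of amplitude, MESOR, pseudo-F and beta; a
robust-z outlier rule; Benjamini–Hochberg correction across all
interaction tests; and the 7 × 5 baseline Spearman correlation matrix
between cosinor and non-parametric indicators.

## Worked example

```python
from rarlab import (SubjectSpec, simulate_subject, nonparam_summary,
                    cosinor_summary)

spec = SubjectSpec()          # dementia-like defaults
series = simulate_subject(spec, days=7, seed=42)
np_res = nonparam_summary(series)
cos = cosinor_summary(series)

print(f"IS  = {np_res.IS:.3f}   IV = {np_res.IV:.3f}   RA = {np_res.RA:.3f}")
print(f"L5  = {np_res.L5:.1f} counts (onset {np_res.L5_onset:.2f} h)")
print(f"M10 = {np_res.M10:.1f} counts (onset {np_res.M10_onset:.2f} h)")
print(f"acrophase = {cos['acrophase']:.2f} h   amplitude = {cos['amplitude']:.1f}")
print(f"MESOR = {cos['mesor']:.1f}   alpha = {cos['alpha']:.2f}   "
      f"beta = {cos['beta']:.2f}   pseudo-F = {cos['pseudo_F']:.0f}")
```

prints

```
IS  = 0.676   IV = 0.633   RA = 0.701
L5  = 18.7 counts (onset 1.25 h)
M10 = 106.1 counts (onset 10.87 h)
acrophase = 16.05 h   amplitude = 120.1
MESOR = 71.0   alpha = 0.15   beta = 2.46   pseudo-F = 1136
```

This simulated resident has a moderately stable (IS 0.68), fragmented
(IV 0.63) rhythm with a clear but imperfect day–night contrast (RA 0.70):
night-time activity averages 19 counts/min from 01:15, daytime activity
106 counts/min from about 10:52. The fitted peak falls at 16:03 decimal
hours — a delayed acrophase typical of dementia cohorts — and the large
pseudo-F says a 24 h periodic model fits far better than a flat mean.

The same computations run from the shell:

```sh
rarlab simulate --config cohort.yaml --out data/
rarlab validate data/epochs/S001_wave00.csv
rarlab nonparam data/epochs/*.csv --out nonparam.csv
rarlab cosinor  data/epochs/*.csv --out cosinor.csv
rarlab trial --epochs data/epochs --covariates data/covariates.csv --out report/
```

`rarlab trial` writes `table3_correlations.csv` (35 Spearman cells),
`table4_interactions.csv` (12 outcomes × 3 follow-up waves with B, 95% CI,
p, BH-adjusted p, ICC and variance explained), a run log of every
exclusion, and a machine-readable manifest.

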