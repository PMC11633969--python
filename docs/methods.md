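# Methods

## Problem and model

Field studies that record personal light exposure with wearable loggers
produce nested time series: epochs within days within participants.  The
question the package answers is *how many participants are needed* to
detect a condition effect (e.g. winter vs. summer) on a chosen daily
light-exposure metric with a given statistical power.

The analysis model is a Gaussian random-intercept linear mixed model per
metric *i*:

    Metric_i = alpha_i + beta_i * 1[condition = contrast] + b_p,i + e,
    b_p,i ~ N(0, sigma_b,i^2),   e ~ N(0, sigma_i^2)

with treatment coding (the first configured condition level is the
reference, so `beta` is the expected change of the metric in the contrast
condition).  Random slopes are deliberately excluded: across tens of
thousands of bootstrap fits, slope models fail to converge too often to
be usable, and the day-level metric values within a participant-condition
cell are treated as exchangeable.

Power is estimated by a **two-level bootstrap** of the historical (or
synthetic) daily-metrics table.  For a target sample size `n`:

1. draw `n` participants with replacement; each draw becomes a fresh
   pseudo-participant (so the model always sees `n` groups);
2. within every pseudo-participant and condition, redraw that cell's days
   with replacement, preserving the cell size.

Each resample is fitted and the condition effect tested at
`alpha_level = 0.05`; power at `n` is the fraction of `m` resamples with
a significant effect, and the required sample size is the smallest `n`
with power at or above the 0.8 threshold.  Resampling both levels
propagates the inter-individual *and* intra-individual variance captured
by the source data, and makes the implied effect size metric-specific —
no external effect-size guess enters the procedure.

## Pipeline and parameters

Raw logger CSVs are mapped through a schema config, snapped onto a
regular epoch grid (dominant-epoch detection; ties are an error and
require an explicit epoch), and filtered:

* a participant-day is kept only if >= 80% of its grid cells are valid
  (worn and non-missing); the comparison is inclusive at the boundary;
* a participant is kept only with >= 2 valid days in *every* condition.

Melanopic EDI is computed from green/blue sensor irradiances as
`4.3 * (G + B) / 1.3262` lx when not already present.  Non-wear epochs on
kept days are excluded from metric computations rather than zero-filled
(light hitting a shelved device is not personal exposure); a
`zero_fill_nonwear` switch exposes the alternative for sensitivity
analysis.

Twelve daily metrics are computed per participant-day (geometric mean and
SD on log10 with a 0.01 lx floor, luminous exposure, time above 250 and
1000 lx, mean timing of light above 250 / below 10 lx, intradaily
variability, and the mean/midpoint of the brightest 10 h and darkest 5 h
windows).  Numerical conventions, chosen where the field has no single
standard and applied consistently:

* threshold comparisons are strict (`>` above, `<` below); with
  continuous sensor values the boundary has measure zero;
* mean timing uses the linear mean of epoch-midpoint clock hours on a
  midnight-anchored day (circular mean available as an option);
* intradaily variability is the Van Someren first-order-difference ratio
  on hourly means; empty hourly bins are dropped and successive
  differences are taken only between clock-adjacent bins; a constant day
  (zero variance) yields a missing value;
* M10/L5 windows slide in epoch steps, never wrap midnight, need >= 50%
  valid cells to be scoreable, and break ties toward the earliest window;
* the 0.01 lx log floor sits below typically observed darkest-5-h means
  (~0.05 lx) so it truncates only true-zero night readings.

A metric that is undefined on a day (e.g. no epoch above 250 lx) is a
missing cell; fits drop missing rows.

## Estimation and inference

The random-intercept model is estimated by REML, profiled over the
variance ratio `lambda = sigma_b^2 / sigma^2`: with per-group sufficient
statistics, the GLS fixed effects, the residual variance and the whole
REML criterion are closed-form for any `lambda`, reducing a fit to a
bounded 1-D optimization.  This keeps a single fit near a millisecond,
which is what makes `m = 1000` resamples across 48 sample sizes and 12
metrics (576,000 fits) tractable on one core.

The condition effect is tested with a t statistic whose degrees of
freedom are Satterthwaite-approximated from the REML curvature:
`df = 2 Var(beta_hat)^2 / (g' A g)` with `g` the gradient of
`Var(beta_hat)` in the variance components and `A` the inverse negative
Hessian of the REML log-likelihood (finite differences; one-sided at the
`sigma_b^2 = 0` boundary).  Wald-z inference is anticonservative with
3-10 groups — exactly the region where required sample sizes are decided
— and would bias them.  The implementation is validated against R's
lmerTest on frozen fixtures (agreement to ~6 significant digits in
estimates, SEs, df and p-values, including boundary and 3-group cases)
and against statsmodels MixedLM for the point estimates; its size over
iid draws of the null generative model at n = 15 is 0.04-0.05.

Degenerate resamples (a condition entirely missing, fewer than 2 groups,
zero residual variance) return a non-converged fit; such replicates count
as **not significant** with the denominator kept at `m`, and are tallied
in `n_failed`.  Dropping them instead would inflate power at small `n`,
where failures concentrate.  Boundary fits (`sigma_b^2 = 0`) are legal,
flagged singular, and retained.

Randomness is counter-based: replicate `j` at size `n` for a given metric
uses `SeedSequence(metric_sub_seed, spawn_key=(n, j))`, where the metric
sub-seed is a 31-bit hash of (run seed, metric name).  Any replicate is
reproducible in isolation and results are independent of scheduling and
worker count.

## Synthetic data

Two generator tiers define the study conditions for testing:

* **day-metric tier** — draws metric values directly from the generative
  random-intercept model; used for calibration, parameter recovery and
  power-behaviour studies.  Default scale: 13 participants with 2-5 days
  per condition, matching a realistic field cohort.
* **epoch tier** — square-wave diurnal profiles (dim ~0.05 lx night,
  bright plateau between lights-on and lights-off) per condition,
  multiplied by lognormal epoch noise (0.2 log10 units) and a lognormal
  participant level (0.15 log10 units, the random intercept on the log
  scale), with optional non-wear blocks.  Defaults loosely mimic a
  central-European winter/summer contrast for day workers (winter ~70 lx
  07:00-17:00, summer ~400 lx 06:00-20:00).

The epoch tier emulates diurnal structure, participant heterogeneity,
seasonal contrast and non-wear gaps; it does **not** emulate weather,
weekday/weekend structure, gradual dawn/dusk ramps, or spectral sensor
behaviour.  Tests passing on it therefore demonstrate correctness of the
computational pipeline and the statistical machinery under the assumed
variance structure, not fidelity of any particular field dataset.

## Problem sizes used in tests and the acceptance script

Test and acceptance runs use reduced designs chosen to keep the evidence
meaningful at desk scale: calibration uses a 500-participant null pool
(a small pool's nonzero empirical seasonal difference would confound the
test's size with the pool's sampling noise), `m = 1000` at `n = 15`;
parameter recovery uses 200 participants x 4 days/condition; power
monotonicity uses a 13-participant pool, `m = 500`, `n = 3..30`; metric
oracle checks use 200 random synthetic days at 5-min epochs.

## Known limitations

* **Small-cell anticonservatism of the two-level bootstrap.**  The
  day-level redraw duplicates days inside small cells; with 2-day cells
  the expected within-cell variance of a resample is half the empirical
  one, while the resample-to-resample spread of the effect estimate
  grows.  The net effect: although the mixed-model test itself is
  calibrated (size ~0.05 over iid draws), the *full procedure's*
  rejection rate under a null pool is ~0.13-0.18 at 2 days per cell
  (confirmed independently by rerunning the identical resampling scheme
  through lme4/lmerTest).  The bias shrinks as cells grow (factor
  (d-1)/d).  Consequence: power estimates — and the published-style
  required sample sizes — are optimistic for designs with very few days
  per participant-condition cell.  Cluster-level-only resampling is
  calibrated, but discards the intra-individual variance the method
  exists to propagate; resolving this tension (e.g. d-1-out-of-d or
  rescaled day redraws) is future work, not silently applied.
* The procedure estimates power only for effects on light-exposure
  metrics themselves, not for downstream outcomes (sleep, alertness).
* Required-sample-size estimates inherit the effect size of the source
  dataset; they are only as generalizable as that cohort.
* DST days keep their wall-clock grid (23/25 h); metrics are computed on
  actual grid content without renormalization.
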