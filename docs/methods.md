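# Methods

## The model

`lekmix` fits open-population (dynamic) N-mixture models to repeated
counts of unmarked birds on leks.  Site `i` (a lek) in season `t` holds a
latent abundance `N_it`; visit `j` produces a count

    y_itj ~ Binomial(N_it, p_itj)

with detection probability `p_itj` on the logit scale.  The first season
draws `N_i1` from an initial mixture with mean `lambda_i` (log link):
Poisson, zero-inflated Poisson (extra point mass `psi` at zero, logit
link), or negative binomial (dispersion `alpha`, log link; variance
`lambda + lambda^2/alpha`).  Subsequent seasons follow the
survivor-plus-recruit decomposition

    N_it = S_it + G_it,
    S_it ~ Binomial(N_i,t-1, omega_it)        apparent survival (logit)
    G_it ~ Poisson(gamma_it)                  constant dynamics (log)
    G_it ~ Poisson(gamma_it * N_i,t-1)        autoregressive dynamics

Apparent survival confounds death with emigration, and recruitment births
with immigration; the model separates neither, which is the appropriate
reading for trend work on count data alone.

The marginal likelihood integrates the latent chain with a forward
(filtering) recursion over the truncated state space `{0, ..., K}`.  All
probability mass above `K` is folded into state `K`, so every transition
row sums to one.  Missing visits drop out of the binomial product; a
season with no visits contributes only through the dynamics.

## Truncation

`K` defaults to the maximum observed count plus 20.  `truncation_check`
re-evaluates the fitted NLL at `K + 10`; on every simulated survey we
use, the difference is far below 1e-6, confirming no posterior mass
presses against the bound even in boom years.  Users with strong booms
(counts near `K`) should raise `K` and re-check.

## Covariates and standardization

All demographic and detection covariates are z-scored before entering
the linear predictors, and the constants are stored on the fit for
back-transformation (`predict_effect` accepts grids in original units).
Year-level demographic covariates are standardized over the transition
seasons (years 2..T); "same year" always means the covariate measured in
the season being entered, and `*_lag1` columns carry the prior year's
value.  Covariate values missing for a season are imputed at the mean
(0 after z-scoring) and, in the grazing analysis, the corresponding
counts are masked so the season informs the fit only through the
dynamics.

Year-level weather covariates: annual precipitation (cm), mean and
minimum modified Palmer Drought Index (PMDI; negative = drier), annual
maximum temperature (deg C), and hot days — the count of days whose
daily maximum exceeds the long-run 90th percentile (35 deg C for this
system, strict inequality).  Seasonal aggregates use winter =
Dec(t-1)-Feb(t), breeding = Mar-May, summer = Jun-Aug, fall = Sep-Nov;
an incomplete season yields a missing value, never a partial total.
Grazing pressure is cow days/ha = cattle x days grazed / pasture area,
summed over within-year rotations; a lek spanning several pastures gets
the area-weighted mean.

## Numerics

The forward recursion assembles detection terms on the log scale and
rescales by the running maximum at each season — the stable evaluation
of the log-sum-exp chain without building per-step logarithm tables.
Two details matter in practice:

* **Tail folding.** The folded column `P(N_t >= K | N_{t-1} = a)` is
  computed from the Poisson survival function (a backward cumsum of the
  pmf grid plus the beyond-grid tail), not as `1 - rowsum`.  The naive
  difference leaves cancellation noise of order 1e-16 that flips
  discontinuously with microscopic parameter changes; for surveys whose
  histories are nearly impossible under a candidate model, that noise can
  rival the true path mass and break quasi-Newton line searches.
* **Finite objective.** The per-season normalizer is floored at 1e-300,
  so parameter regions that annihilate all forward mass return a very
  large finite NLL instead of an infinite wall.

Convolutions for the transition kernel are computed exactly (an FFT
variant is faster at large `K` but rounds the smallest transition
probabilities to zero, reintroducing cliffs); the inner loop uses a
numba-compiled kernel when numba is available, with an identical
vectorized numpy fallback otherwise.  Kernels are built in one batched
call per likelihood evaluation, de-duplicated across seasons and sites,
and the detection/initial/transition blocks are memoized on their own
parameter sub-vectors so finite-difference gradient steps rebuild only
the block they perturb.

## Fitting and inference

Maximum likelihood by L-BFGS-B on the mean NLL per observation (so
gradients are O(1) against the unit initial Hessian guess), gradient
tolerance 1e-8 and relative objective tolerance 1e-9 (which locates the
NLL far below AIC resolution), from a deterministic moment-flavoured
start plus seeded jittered restarts (default 3 starts).  Standard errors come from the
inverse of a numerically differentiated Hessian of the full NLL; a
non-positive-definite Hessian marks the fit non-converged and leaves the
SEs undefined — such models are excluded from CI-based screening and get
zero Akaike weight, never silently zeroed.  Wald 95% intervals are
`estimate ± 1.959964 SE`; effect curves apply the delta method on the
link scale and back-transform, so probability-scale curves stay in
[0, 1].

Autoregressive dynamics have a known weakly identified ridge
(`omega -> 0` with `gamma` near the population growth rate — total
replacement instead of survival).  Covariate scans, which warm-start each
candidate from the intercept-only optimum of the matching dynamics,
detect suspicious solutions (non-PD Hessian or a demographic intercept
beyond |5| on the link scale) and retry from the cold default start,
keeping the better optimum.

## Model building

The four-step procedure mirrors standard practice for these surveys:

1. **Family** — intercept-only nulls under Poisson/ZIP/NB, ranked by AIC
   (ties broken toward fewer parameters, then name).
2. **Detection screen** — a single global model with daily rainfall,
   daily maximum temperature, and effort (the z-scored number of visits);
   covariates whose 95% CI touches or crosses 0 are dropped.  The screen
   is single-pass (no drop-and-refit).
3. **Initial abundance** — the maximum count of the season preceding the
   first modeled year, same CI rule; leks without a prior count carry the
   covariate mean and are flagged.
4. **Demographic scan** — exactly one covariate per model, on recruitment
   (autoregressive dynamics) or survival (constant dynamics).  The annual
   menu is the 20-model set (5 variables x same-year/1-year-lag x 2
   processes); the seasonal menu adds seasonal precipitation and PMDI,
   with lagged seasonal terms restricted to summer and fall.  Ranking by
   AIC by default (AICc is computed and selectable); Akaike weights are
   reported both over the full candidate set and within each process,
   since a single weight scope cannot serve both readings.

The grazing assessment splits the series at the severe-drought year
(2011 labels; the split year belongs to the during/postdrought window)
and fits cow days/ha on recruitment and on survival within each window.
Because the same covariate acts on both processes in the joint generating
truth, each single-covariate model absorbs part of the other process's
effect; signs and CI exclusion are the reliable readings, exactly as the
scan reports them.

## Abundance series and contrast

Annual abundance is the empirical-Bayes posterior of `N_it` given the
complete count history of each lek (forward-backward smoothing at the
MLE) — smoothing rather than filtering because abundance is reported
retrospectively.  The per-year value is the cross-lek mean of posterior
means over the leks surveyed that year (totals are also emitted).
Year-level 95% intervals come from a seeded parametric bootstrap (500
draws by default) that resamples the coefficient vector from its
asymptotic normal and re-derives the smoothed series; the same draws feed
the fold-change interval.  The pre/post contrast is a one-way
fixed-effects ANOVA on the annual values, df = (1, T-2); identical group
means return F = 0 by definition.  A zero post-period mean makes the
fold change infinite with a flag, never an error.

## The synthetic-data generator

The generator emulates the study design the analysis assumes: 49 leks,
12 seasons labelled 2004-2015, 1-5 flush counts per lek-season between
mid-March and late April, detection driven by simulated visit weather
and effort through the same links the model uses, and latent abundance
following the survivor/recruit decomposition.  Year covariates come from
the packaged Table-1-style fixture (optionally Gaussian-perturbed, 5% of
the column SD by default) or a fully parametric mode; monthly series
consistent with the annual values supply the seasonal aggregates, and
pasture-level grazing records are generated so the derived cow days/ha
track the fixture's annual scale, with the 2012 record missing as in the
source data.  Latent truth (every `N_it` and all generating parameters)
is returned beside the data so recovery tests never re-simulate.

Default truth: `lambda` = 8 birds/lek, `p` = 0.6, `omega` = 0.65,
autoregressive `gamma` = 0.30.  The drought scenario
(`gamma0` = 0.20, `omega0` = 0.60, hot-days log slope -1.0 on
recruitment, PMDI logit slope +0.8 on survival) was calibrated once by a
deterministic expected-trajectory search so the predrought:postdrought
mean abundance ratio is ~7 under the fixture weather while counts stay
on the observed scale (~8 early, ~1 late).  The grazing scenario reuses
the printed predrought coefficients (logit 0.54 on survival, log 0.19 on
recruitment, per SD of cow days/ha) as generating truth over the seven
predrought seasons.

What the generator does **not** emulate: spatial dependence between
leks, observer heterogeneity, within-season population turnover, the
exact visit-date distribution of the real surveys, and real weather
autocorrelation structure beyond the fixture values.  Passing recovery
tests therefore demonstrate the estimator works when its assumptions
hold at the study's design scale — not that those assumptions hold in
any particular field dataset.

## Problem sizes used in the test bench

The statistical acceptance tests run at the full design scale (M = 49,
T = 12): 25 recovery replicates, 20 selection-power replicates over the
10-candidate annual recruitment menu, 20 + 20 grazing replicates
(effect and null), and 20 drought-pipeline replicates.  Scan fits use a
single warm-started quasi-Newton run (the package default for `fit` is
3 starts); the pipeline test skips the bootstrap interval since only the
ratio and the ANOVA enter the check.  Unit tests use smaller surveys
(M = 8-30, T = 4-8) and brute-force oracles with K = 8-25.

## Known limitations

* Apparent survival and per-capita recruitment are weakly separated when
  year-to-year variation is large; the scan's ridge guard mitigates but
  cannot remove the identifiability limit.
* AIC ranking with one covariate at a time cannot attribute effects that
  genuinely act on both processes (see the grazing note above).
* Wald intervals can misbehave near boundaries (omega or p near 0/1);
  the non-PD flag catches most such fits.
* The NB-vs-Poisson nesting gap at `alpha = 1e6` is a genuine
  O(M lambda^2 / alpha) offset of the initial-year pmf, visible at
  large survey sizes; it is a property of the parameterization, not an
  implementation error.
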