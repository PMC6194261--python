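# lekmix

Open-population N-mixture models for repeated lek counts: abundance,
apparent survival, and recruitment for boom–bust grouse populations under
drought and grazing covariates.

## The problem

Lek-count surveys visit each communal display ground several times per
breeding season and flush-count the birds present.  Counts miss birds
(detection < 1) and abundance changes between seasons, so raw counts
conflate detection, survival, and recruitment.  `lekmix` fits the
dynamic N-mixture model for such data: latent lek abundance N_it with

* N_i1 ~ Poisson / zero-inflated Poisson / negative binomial, mean λ_i,
* N_it = S_it + G_it with S_it ~ Binomial(N_i,t−1, ω_it) survivors and
  G_it ~ Poisson(γ_it) recruits (or Poisson(γ_it·N_i,t−1) under
  autoregressive dynamics),
* y_itj ~ Binomial(N_it, p_itj) per visit,

with log/logit links on covariates, maximum-likelihood fitting over a
truncated latent grid, and Wald inference.  On top of the likelihood
sit the field's standard workflow pieces: AIC model building (family →
detection screen → initial-abundance screen → single-covariate
demographic scans), Akaike weights, empirical-Bayes abundance series,
a pre/post-drought ANOVA contrast with fold change, and a synthetic
survey generator that emulates a 49-lek, 12-season Southern High Plains
monitoring design — so the whole pipeline is testable end to end with
known truth.  See `docs/methods.md` for the model and numerics.

## Worked example

```python
import numpy as np
from lekmix import (ModelSpec, fit, simulate, drought_scenario,
                    posterior_abundance, anova_pre_post, fold_change)

sim = simulate(drought_scenario(seed=3))     # 49 leks, 2004-2015 labels
spec = ModelSpec("poisson", "autoregressive",
                 gamma_covariates=("hot_days",),
                 omega_covariates=("pmdi_avg",))
res = fit(sim.data, sim.covs, spec, starts=1)
print(res.coef("gamma:hot_days"), res.coef_ci("gamma:hot_days"))

series = posterior_abundance(res, sim.data, sim.covs, interval_draws=200,
                             seed=1)
an = anova_pre_post(series, split_year=2011)
fc = fold_change(series, split_year=2011)
print(f"F({an.df1},{an.df2}) = {an.F:.2f}, p = {an.p:.4f}")
print(f"fold change = {fc.ratio:.2f} [{fc.lo95:.2f}, {fc.hi95:.2f}]")
```

Output:

```
-0.9652062810296047 (-1.2598802857078826, -0.6705322763513267)
F(1,10) = 79.89, p = 0.0000
fold change = 6.95 [6.81, 7.08]
```

The fitted hot-days slope (−0.97, CI −1.26 to −0.67) recovers the
generating truth of −1.0: each additional standard deviation of hot
days multiplies per-capita recruitment by e^β ≈ 0.37.  The ANOVA
contrasts mean annual abundance over 2004–2010 against 2011–2015 with
the df = (1, 10) structure of a 12-year split, and the fold change says
predrought abundance was ~7× postdrought abundance, with a parametric-
bootstrap interval.

A command-line workflow wraps the same stages:

```bash
lekmix simulate --config run.yaml --seed 3 --out run/
lekmix select   --config run.yaml --out run/        # four-step + grazing scan
lekmix estimate --config run.yaml --out run/        # series, ANOVA, fold change
lekmix report   --summary run/abundance_year_summary.csv
```

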