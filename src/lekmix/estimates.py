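"""Annual abundance series and the pre/post-drought contrast.

Abundance is reported as the empirical-Bayes posterior of the latent lek
abundance N_it given the complete count history of each lek (forward-
backward smoothing at the maximum-likelihood parameter estimates).
Year-level uncertainty comes from a seeded parametric bootstrap that
resamples the coefficient vector from its asymptotic normal distribution
and re-derives the smoothed series for every draw.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import NMixtureLikelihood
from .types import CountData, CovariateTable, DataError, FitError, FitResult

__all__ = ["AbundanceSeries", "posterior_abundance", "anova_pre_post",
           "fold_change", "AnovaResult", "FoldChange"]


@dataclass
class AbundanceSeries:
    """Smoothed abundance per (lek, year) and the cross-lek annual summary.

    ``site_year`` holds the posterior mean and central 95% interval of
    N_it.  ``year_summary`` averages the posterior means over the leks
    surveyed that year (``mean``) and also reports the cross-lek total;
    its interval columns come from the parametric bootstrap when one was
    run.  ``bootstrap_year_means`` keeps the raw bootstrap draws so later
    contrasts (fold change) reuse the same uncertainty propagation.
    """

    site_year: pd.DataFrame
    year_summary: pd.DataFrame
    years: np.ndarray
    posterior: np.ndarray                       # (M, T, K+1)
    bootstrap_year_means: np.ndarray | None = None   # (draws, T)
    split_year: int | None = None

    def year_values(self, response: str = "mean") -> np.ndarray:
        if response not in ("mean", "total"):
            raise DataError("response must be 'mean' or 'total'")
        return self.year_summary[response].to_numpy(dtype=float)


def _posterior_summary(post: np.ndarray, grid: np.ndarray):
    """Mean and central 95% interval of each discrete posterior."""
    mean = post @ grid
    cdf = np.cumsum(post, axis=-1)
    lo = np.argmax(cdf >= 0.025, axis=-1)
    hi = np.argmax(cdf >= 0.975, axis=-1)
    return mean, lo.astype(float), hi.astype(float)


def _year_means(post: np.ndarray, grid: np.ndarray,
                observed: np.ndarray) -> tuple:
    """Cross-lek mean (over surveyed leks) and total of posterior means."""
    m = post @ grid                                   # (M, T)
    with np.errstate(invalid="ignore"):
        mean = np.where(observed.any(axis=0),
                        (m * observed).sum(axis=0)
                        / np.maximum(observed.sum(axis=0), 1),
                        m.mean(axis=0))
    return mean, m.sum(axis=0)


def posterior_abundance(fitres: FitResult, data: CountData,
                        covs: CovariateTable | None,
                        interval_draws: int = 500,
                        seed: int = 0) -> AbundanceSeries:
    """Empirical-Bayes abundance series from a converged fit.

    ``interval_draws`` > 0 adds year-level 95% intervals via the
    parametric bootstrap (coefficients resampled from N(theta_hat, vcov),
    series re-smoothed per draw); pass 0 to skip.
    """
    if not fitres.converged:
        raise FitError("posterior abundance requires a converged fit")
    ctx = NMixtureLikelihood(data, covs, fitres.spec.replace(K=fitres.K))
    grid = np.arange(fitres.K + 1, dtype=float)
    post = ctx.posterior_latent(fitres.params)
    mean, lo, hi = _posterior_summary(post, grid)
    observed = data.effort > 0
    rows = []
    for i, lek in enumerate(data.site_ids):
        for t, year in enumerate(data.years):
            rows.append((lek, int(year), mean[i, t], lo[i, t], hi[i, t],
                         bool(observed[i, t])))
    site_year = pd.DataFrame(rows, columns=["lek_id", "year", "mean",
                                            "lo95", "hi95", "observed"])
    ymean, ytotal = _year_means(post, grid, observed)
    summary = pd.DataFrame({"year": data.years.astype(int), "mean": ymean,
                            "total": ytotal})

    draws = None
    if interval_draws > 0 and np.all(np.isfinite(fitres.vcov)):
        rng = np.random.default_rng(seed)
        thetas = rng.multivariate_normal(fitres.params, fitres.vcov,
                                         size=interval_draws,
                                         check_valid="ignore")
        draws = np.empty((interval_draws, data.T))
        totals = np.empty((interval_draws, data.T))
        for b in range(interval_draws):
            try:
                pb = ctx.posterior_latent(thetas[b])
            except (FloatingPointError, DataError):
                pb = post
            draws[b], totals[b] = _year_means(pb, grid, observed)
        summary["lo95"] = np.quantile(draws, 0.025, axis=0)
        summary["hi95"] = np.quantile(draws, 0.975, axis=0)
        summary["total_lo95"] = np.quantile(totals, 0.025, axis=0)
        summary["total_hi95"] = np.quantile(totals, 0.975, axis=0)
    return AbundanceSeries(site_year, summary, data.years.astype(int), post,
                           bootstrap_year_means=draws)


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    group_means: dict = field(default_factory=dict)


def _split_groups(series: AbundanceSeries, split_year: int,
                  response: str, include_split_in: str) -> tuple:
    vals = series.year_values(response)
    years = series.years
    post_mask = years >= split_year if include_split_in == "post" \
        else years > split_year
    return vals[~post_mask], vals[post_mask]


def anova_pre_post(series: AbundanceSeries, split_year: int,
                   response: str = "mean",
                   include_split_in: str = "post") -> AnovaResult:
    """One-way fixed-effects ANOVA of annual abundance between periods.

    One value per year; two groups split at ``split_year`` (which belongs
    to the during/postdrought group by default, matching how the severe
    drought season is grouped).  df = (1, T - 2).
    """
    pre, post = _split_groups(series, split_year, response, include_split_in)
    if len(pre) < 2 or len(post) < 2:
        raise DataError("each period needs at least 2 years for the ANOVA")
    grand = np.mean(np.concatenate([pre, post]))
    ssb = (len(pre) * (np.mean(pre) - grand) ** 2
           + len(post) * (np.mean(post) - grand) ** 2)
    if ssb == 0.0:          # identical group means: F = 0 by definition
        F, p = 0.0, 1.0
    else:
        with np.errstate(invalid="ignore"):
            F, p = stats.f_oneway(pre, post)
    return AnovaResult(float(F), 1, len(pre) + len(post) - 2, float(p),
                       {"pre": float(np.mean(pre)),
                        "post": float(np.mean(post))})


@dataclass
class FoldChange:
    ratio: float
    lo95: float | None
    hi95: float | None
    infinite: bool
    pre_mean: float
    post_mean: float


def fold_change(series: AbundanceSeries, split_year: int,
                response: str = "mean",
                include_split_in: str = "post") -> FoldChange:
    """Ratio of mean predrought to mean during/postdrought annual abundance.

    The 95% interval propagates parameter uncertainty through the
    bootstrap draws stored on the series (if any).  A zero postdrought
    mean is reported as an infinite ratio with a flag, never an error.
    """
    pre, post = _split_groups(series, split_year, response, include_split_in)
    pre_m, post_m = float(np.mean(pre)), float(np.mean(post))
    if post_m == 0.0:
        return FoldChange(float("inf"), None, None, True, pre_m, post_m)
    ratio = pre_m / post_m
    lo = hi = None
    if series.bootstrap_year_means is not None and response == "mean":
        years = series.years
        post_mask = years >= split_year if include_split_in == "post" \
            else years > split_year
        bm = series.bootstrap_year_means
        num = bm[:, ~post_mask].mean(axis=1)
        den = bm[:, post_mask].mean(axis=1)
        r = np.divide(num, den, out=np.full(len(num), np.inf),
                      where=den > 0)
        lo, hi = (float(np.quantile(r, 0.025)), float(np.quantile(r, 0.975)))
    return FoldChange(float(ratio), lo, hi, False, pre_m, post_m)
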