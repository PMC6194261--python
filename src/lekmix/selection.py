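"""Four-step model building and ranked candidate tables.

The analysis workflow screens model structure before scanning ecological
covariates:

1. choose the initial-abundance family (Poisson / zero-inflated Poisson /
   negative binomial) by AIC among intercept-only null models;
2. screen the global detection model (daily rainfall, daily maximum
   temperature, effort) and keep covariates whose Wald 95% CI excludes 0;
3. test the prior season's lek count as an initial-abundance predictor
   with the same CI rule;
4. scan single-covariate weather models on recruitment (autoregressive
   dynamics) or survival (constant dynamics), one covariate per model,
   ranked by AIC with Akaike weights.

The grazing assessment applies the step-4 machinery to cow days/ha within
the predrought and during/postdrought windows separately.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import ANNUAL_WEATHER
from .fit import FitOptions, fit
from .types import (CountData, CovariateTable, DataError, FitError,
                    FitResult, ModelSpec)

__all__ = ["Candidate", "annual_weather_menu", "seasonal_weather_menu",
           "full_weather_menu", "akaike_weights", "step1_distribution",
           "step2_screen_detection", "step3_initial_abundance",
           "step4_demographic_scan", "weather_scan", "grazing_scan",
           "four_step", "FourStepResult"]

PROCESSES = ("recruitment", "survival")
SAME, LAG = "same year", "year before"


@dataclass(frozen=True)
class Candidate:
    """One single-covariate demographic model in a scan."""

    process: str            # "recruitment" -> gamma, "survival" -> omega
    covariate: str          # base column name in the year table
    period: str = SAME      # "same year" | "year before"

    @property
    def column(self) -> str:
        return self.covariate + ("_lag1" if self.period == LAG else "")

    @property
    def label(self) -> str:
        return f"{self.process}:{self.covariate}:{self.period}"


def annual_weather_menu() -> list:
    """The 20 annual weather models: 5 variables x {same year, 1-yr lag}
    x {recruitment, survival}."""
    return [Candidate(proc, v, per) for proc in PROCESSES
            for v in ANNUAL_WEATHER for per in (SAME, LAG)]


def seasonal_weather_menu() -> list:
    """Seasonal precipitation and PMDI models.

    All four seasons enter in the same year; lagged seasonal effects are
    restricted to summer and fall (winter/spring of the year before are
    assumed too distant to act on the population).
    """
    out = []
    for proc in PROCESSES:
        for var in ("precip", "pmdi"):
            for season in ("winter", "breeding", "summer", "fall"):
                out.append(Candidate(proc, f"{var}_{season}", SAME))
            for season in ("summer", "fall"):
                out.append(Candidate(proc, f"{var}_{season}", LAG))
    return out


def full_weather_menu() -> list:
    return annual_weather_menu() + seasonal_weather_menu()


def akaike_weights(aic_values) -> np.ndarray:
    """w_i = exp(-Delta_i / 2) / sum_k exp(-Delta_k / 2)."""
    a = np.asarray(aic_values, dtype=float)
    if a.size == 0:
        raise DataError("empty AIC list")
    if not np.all(np.isfinite(a)):
        raise DataError("AIC values must be finite")
    w = np.exp(-(a - a.min()) / 2.0)
    return w / w.sum()


def _ci_excludes_zero(fitres: FitResult, name: str) -> bool:
    """Strict exclusion: an interval touching 0 counts as overlapping."""
    lo, hi = fitres.coef_ci(name)
    return bool(np.isfinite(lo) and np.isfinite(hi) and (lo > 0 or hi < 0))


# ---------------------------------------------------------------------------
@dataclass
class Step1Result:
    family: str
    table: pd.DataFrame
    fits: dict


def step1_distribution(data: CountData, covs: CovariateTable | None,
                       options: FitOptions | None = None) -> Step1Result:
    """Pick the count distribution by AIC among intercept-only null models.

    Ties break toward fewer parameters (Poisson before ZIP/NB), then
    alphabetically.  Non-converged nulls are excluded with a warning.
    """
    rows, fits = [], {}
    for family in ("poisson", "zip", "negbin"):
        spec = ModelSpec(initial_family=family, dynamics="constant")
        try:
            r = fit(data, covs, spec, options)
        except FitError:
            warnings.warn(f"null model for family {family!r} failed to fit")
            continue
        if not r.converged:
            warnings.warn(f"null model for family {family!r} did not "
                          "converge; excluded from family selection")
        fits[family] = r
        rows.append({"family": family, "n_params": r.n_params,
                     "nll": r.nll, "aic": r.aic, "aicc": r.aicc,
                     "converged": r.converged})
    table = pd.DataFrame(rows)
    usable = table[table["converged"]]
    if usable.empty:
        raise FitError("no null model converged; cannot select a family")
    best = usable.sort_values(["aic", "n_params", "family"]).iloc[0]
    table = table.sort_values(["aic", "n_params", "family"],
                              ignore_index=True)
    table["dAIC"] = table["aic"] - best["aic"]
    return Step1Result(str(best["family"]), table, fits)


@dataclass
class Step2Result:
    retained: tuple
    fit: FitResult | None
    table: pd.DataFrame


def step2_screen_detection(data: CountData, covs: CovariateTable | None,
                           family: str,
                           options: FitOptions | None = None) -> Step2Result:
    """Single-pass screen of the global detection model.

    Fits detection with daily rainfall, daily maximum temperature, and
    effort together, then keeps covariates whose Wald 95% CI excludes 0.
    If the global model fails, detection falls back to intercept-only.
    """
    p_covs = ("daily_rain", "daily_tmax", "effort")
    spec = ModelSpec(initial_family=family, dynamics="constant",
                     p_covariates=p_covs)
    try:
        r = fit(data, covs, spec, options)
    except FitError:
        r = None
    if r is None or not r.converged:
        warnings.warn("global detection model did not converge; "
                      "falling back to intercept-only detection")
        return Step2Result((), r, pd.DataFrame())
    rows = []
    for name in p_covs:
        lo, hi = r.coef_ci(f"p:{name}")
        rows.append({"covariate": name, "beta": r.coef(f"p:{name}"),
                     "lcl": lo, "ucl": hi,
                     "retained": _ci_excludes_zero(r, f"p:{name}")})
    table = pd.DataFrame(rows)
    retained = tuple(table.loc[table["retained"], "covariate"])
    return Step2Result(retained, r, table)


@dataclass
class Step3Result:
    retained: bool | None       # None = step skipped (no prior-year data)
    fit: FitResult | None
    note: str = ""


def step3_initial_abundance(data: CountData, covs: CovariateTable,
                            family: str, detection_set=(),
                            options: FitOptions | None = None) -> Step3Result:
    """Test the prior season's maximum lek count as a lambda predictor.

    Leks without a prior-season count carry the covariate at its mean
    (0 after z-scoring) and are flagged; if no lek has prior data the step
    is skipped with a notice.
    """
    prior = covs.site.get("prior_count")
    if prior is None or np.all(np.isnan(np.asarray(prior, dtype=float))):
        return Step3Result(None, None,
                           "no prior-season counts available; step skipped")
    prior = np.asarray(prior, dtype=float)
    if np.nanstd(prior) == 0:
        warnings.warn("prior-season counts are constant; covariate "
                      "degenerate after z-scoring and dropped")
        return Step3Result(False, None, "degenerate prior-count covariate")
    spec = ModelSpec(initial_family=family, dynamics="constant",
                     lambda_covariates=("prior_count",),
                     p_covariates=tuple(detection_set))
    r = fit(data, covs, spec, options)
    note = ""
    if np.isnan(prior).any():
        note = (f"{int(np.isnan(prior).sum())} leks lack a prior-season "
                "count; covariate imputed at the mean")
    if not r.converged:
        warnings.warn("prior-count model did not converge; covariate dropped")
        return Step3Result(False, r, "non-converged prior-count model")
    return Step3Result(_ci_excludes_zero(r, "lambda:prior_count"), r, note)


# ---------------------------------------------------------------------------
def _candidate_spec(base: ModelSpec, cand: Candidate) -> ModelSpec:
    if cand.process == "recruitment":
        return base.replace(dynamics="autoregressive",
                            gamma_covariates=(cand.column,),
                            omega_covariates=())
    if cand.process == "survival":
        return base.replace(dynamics="constant", gamma_covariates=(),
                            omega_covariates=(cand.column,))
    raise DataError(f"unknown process {cand.process!r}")


def _coef_name(cand: Candidate) -> str:
    block = "gamma" if cand.process == "recruitment" else "omega"
    return f"{block}:{cand.column}"


def _rank_table(rows: list, ranking: str) -> pd.DataFrame:
    """Rank candidates, attach dAIC and Akaike weights.

    Non-converged candidates keep their row but get zero weight and sort
    last.  Weights are reported both over the full converged set and
    within each demographic process.  Tie-break: ranking value, then
    fewer parameters, then label.
    """
    t = pd.DataFrame(rows)
    key = "aicc" if ranking == "aicc" else "aic"
    t = t.sort_values(["converged", key, "n_params", "label"],
                      ascending=[False, True, True, True],
                      ignore_index=True)
    conv = t["converged"].to_numpy(dtype=bool)
    t["dAIC"] = np.nan
    t["weight"] = 0.0
    t["weight_process"] = 0.0
    if conv.any():
        best = t.loc[conv, key].min()
        t.loc[conv, "dAIC"] = t.loc[conv, key] - best
        t.loc[conv, "weight"] = akaike_weights(t.loc[conv, key])
        for proc in t["process"].unique():
            m = conv & (t["process"] == proc).to_numpy()
            if m.any():
                t.loc[m, "weight_process"] = akaike_weights(t.loc[m, key])
    return t


def step4_demographic_scan(data: CountData, covs: CovariateTable,
                           base_spec: ModelSpec, process: str,
                           candidates, ranking: str = "aic",
                           options: FitOptions | None = None):
    """Fit one single-covariate model per candidate on one process.

    Recruitment candidates use autoregressive dynamics, survival
    candidates constant dynamics.  Returns the ranked candidate table and
    the fitted models keyed by candidate label.
    """
    cands = [c if isinstance(c, Candidate) else Candidate(process, *c)
             for c in candidates]
    if any(c.process != process for c in cands):
        raise DataError("candidate process does not match the scan process")
    return _scan(data, covs, base_spec, cands, ranking, options)


def weather_scan(data: CountData, covs: CovariateTable,
                 base_spec: ModelSpec, candidates=None,
                 ranking: str = "aic", options: FitOptions | None = None):
    """Scan the full weather menu over both demographic processes."""
    cands = list(candidates) if candidates is not None else full_weather_menu()
    return _scan(data, covs, base_spec, cands, ranking, options)


def _suspicious_params(r: FitResult) -> bool:
    """Extreme demographic intercepts (|link value| > 5) mark the
    weakly identified omega->0 / total-replacement ridge."""
    return any(abs(r.coef(f"{b}:(Intercept)")) > 5.0
               for b in ("gamma", "omega"))


def _suspicious(r: FitResult) -> bool:
    """Ridge heuristics for a candidate fit: non-PD Hessian or an
    extreme demographic intercept."""
    return (not r.hessian_pd) or _suspicious_params(r)


def _warm_start(null_fit: FitResult | None, layout,
                data=None) -> np.ndarray | None:
    """Candidate start vector copied from the matching null-model optimum.

    If the null sits on the weakly identified omega->0 ridge, only its
    lambda and detection blocks are reused; the demographic intercepts
    restart at the defaults so candidates are not dragged onto the ridge.
    """
    if null_fit is None:
        return None
    lut = dict(zip(null_fit.names, null_fit.params))
    if _suspicious_params(null_fit):
        with np.errstate(all="ignore"):
            mean_count = float(np.nanmean(data.counts)) if data is not None \
                else 1.0
        lut["omega:(Intercept)"] = 0.85
        lut["gamma:(Intercept)"] = (
            np.log(0.3) if null_fit.spec.dynamics == "autoregressive"
            else np.log(max(mean_count, 0.5)))
    return np.array([lut.get(name, 0.0) for name in layout.names])


def _scan(data, covs, base_spec, cands, ranking, options):
    from .types import ParameterLayout

    rows, fits = [], {}
    opts = options or FitOptions(starts=1)
    # intercept-only fit per dynamics type, reused as a warm start so every
    # candidate optimisation begins near the shared optimum
    nulls: dict = {}
    for dyn in {("autoregressive" if c.process == "recruitment"
                 else "constant") for c in cands}:
        try:
            nf = fit(data, covs,
                     base_spec.replace(dynamics=dyn,
                                       gamma_covariates=(),
                                       omega_covariates=()),
                     FitOptions(**{**opts.__dict__,
                                   "compute_se": False,
                                   "start_values": None}))
            nulls[dyn] = nf
        except FitError:
            nulls[dyn] = None
    for cand in cands:
        if not covs.has(cand.column):
            raise DataError(f"covariate column {cand.column!r} missing "
                            f"from the covariate table")
        spec = _candidate_spec(base_spec, cand)
        name = _coef_name(cand)
        start = _warm_start(nulls.get(spec.dynamics),
                            ParameterLayout.for_spec(spec), data)
        copts = FitOptions(**{**opts.__dict__, "start_values": start})
        try:
            r = fit(data, covs, spec, copts)
            if _suspicious(r):
                # the warm start can sit on the omega~0 / gamma-large
                # ridge of autoregressive dynamics; retry cold
                r2 = fit(data, covs, spec,
                         FitOptions(**{**opts.__dict__,
                                       "start_values": None}))
                if r2.nll < r.nll or (r2.hessian_pd and not r.hessian_pd
                                      and r2.nll < r.nll + 1e-6):
                    r = r2
        except FitError:
            warnings.warn(f"candidate {cand.label} failed to fit")
            rows.append({"process": cand.process, "covariate": cand.covariate,
                         "period": cand.period, "label": cand.label,
                         "n_params": np.nan, "nll": np.nan, "aic": np.nan,
                         "aicc": np.nan, "beta": np.nan, "se": np.nan,
                         "lcl": np.nan, "ucl": np.nan, "converged": False})
            continue
        fits[cand.label] = r
        lo, hi = r.coef_ci(name)
        rows.append({"process": cand.process, "covariate": cand.covariate,
                     "period": cand.period, "label": cand.label,
                     "n_params": r.n_params, "nll": r.nll, "aic": r.aic,
                     "aicc": r.aicc, "beta": r.coef(name),
                     "se": r.coef_se(name), "lcl": lo, "ucl": hi,
                     "converged": r.converged})
    return _rank_table(rows, ranking), fits


# ---------------------------------------------------------------------------
def _subset_period(data: CountData, covs: CovariateTable, years):
    sub = data.subset_years(years)
    idx = np.asarray([int(np.where(data.years == y)[0][0])
                      for y in sub.years])
    sy = {k: v[:, idx] for k, v in covs.site_year.items()}
    return sub, CovariateTable(covs.year, sy, dict(covs.site))


def grazing_scan(data: CountData, covs: CovariateTable,
                 split_year: int = 2011, base_spec: ModelSpec | None = None,
                 ranking: str = "aic", options: FitOptions | None = None
                 ) -> dict:
    """Cow-days/ha effects on recruitment and survival, per drought period.

    Data are split at ``split_year`` (the split year itself belongs to the
    during/postdrought window).  Seasons whose grazing record is entirely
    missing have their counts masked so they inform the fit only through
    the dynamics.  Each period yields a two-row candidate table.
    """
    if "cow_days" not in covs.site_year:
        raise DataError("covariate table has no cow_days lek-year values")
    base = base_spec or ModelSpec()
    out = {}
    periods = {"predrought": data.years[data.years < split_year],
               "postdrought": data.years[data.years >= split_year]}
    for period, years in periods.items():
        if len(years) == 0:     # data cover a single period; scan just it
            continue
        if len(years) < 3:
            raise DataError(f"{period} window has {len(years)} years; "
                            "dynamics are unidentifiable with < 3")
        sub, subcovs = _subset_period(data, covs, years)
        cd = subcovs.site_year["cow_days"]
        missing_years = [int(y) for t, y in enumerate(sub.years)
                         if np.all(np.isnan(cd[:, t]))]
        if len(missing_years) == len(sub.years):
            raise DataError(f"all grazing records missing in the {period} "
                            "window")
        if missing_years:
            sub = sub.mask_years(missing_years)
        cands = [Candidate("recruitment", "cow_days", SAME),
                 Candidate("survival", "cow_days", SAME)]
        table, fits = _scan(sub, subcovs, base, cands, ranking, options)
        table["period_window"] = period
        table["masked_years"] = [missing_years] * len(table)
        out[period] = {"table": table, "fits": fits,
                       "years": [int(y) for y in years]}
    return out


# ---------------------------------------------------------------------------
@dataclass
class FourStepResult:
    family: str
    step1: Step1Result
    detection_set: tuple
    step2: Step2Result
    lambda_set: tuple
    step3: Step3Result
    base_spec: ModelSpec
    weather_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    weather_fits: dict = field(default_factory=dict)

    @property
    def best_label(self) -> str:
        conv = self.weather_table[self.weather_table["converged"]]
        return str(conv.iloc[0]["label"])

    @property
    def best_fit(self) -> FitResult:
        return self.weather_fits[self.best_label]


def four_step(data: CountData, covs: CovariateTable, candidates=None,
              ranking: str = "aic",
              options: FitOptions | None = None) -> FourStepResult:
    """Run the complete four-step model-building procedure."""
    s1 = step1_distribution(data, covs, options)
    s2 = step2_screen_detection(data, covs, s1.family, options)
    s3 = step3_initial_abundance(data, covs, s1.family, s2.retained, options)
    lam_set = ("prior_count",) if s3.retained else ()
    base = ModelSpec(initial_family=s1.family, dynamics="constant",
                     lambda_covariates=lam_set,
                     p_covariates=tuple(s2.retained))
    table, fits = weather_scan(data, covs, base, candidates, ranking,
                               options or FitOptions(starts=1))
    return FourStepResult(s1.family, s1, s2.retained, s2, lam_set, s3,
                          base, table, fits)
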