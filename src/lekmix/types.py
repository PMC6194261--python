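"""Core containers for open-population N-mixture analyses of lek counts.

The sampling design is M leks (sites) surveyed for T consecutive breeding
seasons (primary periods), with 1..J repeat flush counts (secondary visits)
per lek-season.  Latent abundance N_it evolves between seasons through
apparent survival and recruitment; counts are binomial thinnings of N_it.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FAMILIES = ("poisson", "zip", "negbin")
DYNAMICS = ("constant", "autoregressive")

#: visit-level / derived covariates understood by the detection model
DETECTION_COVARIATES = ("daily_rain", "daily_tmax", "effort")


class ConfigurationError(ValueError):
    """Raised when a model references covariates or options that do not exist."""


class DataError(ValueError):
    """Raised when input tables violate the expected schema."""


class FitError(RuntimeError):
    """Raised when every optimisation start fails."""


@dataclass
class CountData:
    """Ragged repeated-count data in rectangular (M, T, Jmax) storage.

    Missing visits are NaN in ``counts`` (and in the visit covariates);
    ``effort[i, t]`` is the number of non-missing visits, so a fully missing
    lek-season has effort 0 and contributes to the likelihood only through
    the population dynamics.
    """

    site_ids: list
    years: np.ndarray            # (T,) calendar year labels, ordered
    counts: np.ndarray           # (M, T, Jmax) float, NaN = missing
    visit_rain: np.ndarray       # (M, T, Jmax) daily rainfall, cm
    visit_tmax: np.ndarray       # (M, T, Jmax) daily max temperature, deg C

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.counts.ndim != 3:
            raise DataError("counts must be (sites, years, visits)")
        if self.counts.shape[:2] != (len(self.site_ids), len(self.years)):
            raise DataError("counts shape does not match site/year labels")
        if np.diff(self.years).min(initial=1) < 1:
            raise DataError("years must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.counts, initial=0) < 0:
                raise DataError("negative counts are not allowed")

    # -- basic dimensions ---------------------------------------------------
    @property
    def M(self) -> int:
        return len(self.site_ids)

    @property
    def T(self) -> int:
        return len(self.years)

    @property
    def effort(self) -> np.ndarray:
        """Number of non-missing visits per (site, year)."""
        return (~np.isnan(self.counts)).sum(axis=2)

    @property
    def max_count(self) -> int:
        m = np.nanmax(self.counts) if np.isfinite(self.counts).any() else 0.0
        return int(m)

    @property
    def n_observations(self) -> int:
        """Total non-missing visit counts (used for AICc)."""
        return int((~np.isnan(self.counts)).sum())

    # -- manipulation -------------------------------------------------------
    def subset_years(self, years) -> "CountData":
        """Restrict to a contiguous subset of seasons (order preserved)."""
        years = np.asarray(sorted(years))
        idx = [int(np.where(self.years == y)[0][0]) for y in years
               if y in self.years]
        if not idx:
            raise DataError("no requested year present in the data")
        sl = np.asarray(idx)
        return CountData(self.site_ids, self.years[sl], self.counts[:, sl],
                         self.visit_rain[:, sl], self.visit_tmax[:, sl])

    def mask_years(self, years) -> "CountData":
        """Return a copy with all visits in ``years`` marked missing."""
        out = CountData(self.site_ids, self.years.copy(), self.counts.copy(),
                        self.visit_rain.copy(), self.visit_tmax.copy())
        for y in years:
            if y in out.years:
                out.counts[:, out.years == y] = np.nan
        return out

    # -- long-format round trip --------------------------------------------
    LONG_COLUMNS = ("lek_id", "year", "visit", "date", "count",
                    "daily_rain_cm", "daily_tmax_c")

    def to_long(self, dates: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for i, lek in enumerate(self.site_ids):
            for t, year in enumerate(self.years):
                for j in range(self.counts.shape[2]):
                    y = self.counts[i, t, j]
                    if np.isnan(y):
                        continue
                    date = "" if dates is None else dates[i, t, j]
                    rows.append((lek, int(year), j + 1, date, int(y),
                                 self.visit_rain[i, t, j],
                                 self.visit_tmax[i, t, j]))
        return pd.DataFrame(rows, columns=self.LONG_COLUMNS)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "CountData":
        missing = [c for c in cls.LONG_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"counts table missing columns: {missing}")
        site_ids = sorted(df["lek_id"].unique())
        years = np.array(sorted(df["year"].unique()))
        jmax = int(df["visit"].max())
        shape = (len(site_ids), len(years), jmax)
        counts = np.full(shape, np.nan)
        rain = np.full(shape, np.nan)
        tmax = np.full(shape, np.nan)
        si = {s: i for i, s in enumerate(site_ids)}
        yi = {int(y): t for t, y in enumerate(years)}
        for row in df.itertuples(index=False):
            i, t, j = si[row.lek_id], yi[int(row.year)], int(row.visit) - 1
            counts[i, t, j] = row.count
            rain[i, t, j] = row.daily_rain_cm
            tmax[i, t, j] = row.daily_tmax_c
        return cls(site_ids, years, counts, rain, tmax)


@dataclass
class CovariateTable:
    """Year-, lek-year- and lek-level covariates with lag metadata.

    ``year`` is indexed by calendar year; lagged columns carry the suffix
    ``_lag1`` and satisfy lagged(t) == unlagged(t-1).  ``site_year`` arrays
    are aligned to a :class:`CountData` (same site order and year order);
    ``site`` arrays carry one value per lek (e.g. the prior-season count
    used as an initial-abundance predictor).
    """

    year: pd.DataFrame = field(default_factory=pd.DataFrame)
    site_year: dict = field(default_factory=dict)
    site: dict = field(default_factory=dict)

    def with_lags(self, columns=None) -> "CovariateTable":
        """Append 1-year-lag columns (value for year t = value at t-1)."""
        tab = self.year.copy()
        for c in (columns or [c for c in tab.columns
                              if not c.endswith("_lag1")]):
            tab[f"{c}_lag1"] = tab[c].shift(1)
        return CovariateTable(tab, dict(self.site_year), dict(self.site))

    def has(self, name: str) -> bool:
        return (name in self.year.columns or name in self.site_year
                or name in self.site)

    def year_values(self, name: str, years) -> np.ndarray:
        """Values of a year-level covariate for the requested years."""
        if name not in self.year.columns:
            raise ConfigurationError(f"unknown year covariate {name!r}")
        return self.year[name].reindex(np.asarray(years, dtype=int)).to_numpy(
            dtype=float)

    def subset_sites(self, index) -> "CovariateTable":
        sy = {k: v[index] for k, v in self.site_year.items()}
        s = {k: v[index] for k, v in self.site.items()}
        return CovariateTable(self.year, sy, s)


@dataclass(frozen=True)
class ModelSpec:
    """Structural definition of one open-population N-mixture model."""

    initial_family: str = "poisson"
    dynamics: str = "constant"
    lambda_covariates: tuple = ()
    gamma_covariates: tuple = ()
    omega_covariates: tuple = ()
    p_covariates: tuple = ()
    K: int | None = None      # latent-abundance truncation; None = auto

    def __post_init__(self):
        if self.initial_family not in FAMILIES:
            raise ConfigurationError(
                f"initial_family must be one of {FAMILIES}")
        if self.dynamics not in DYNAMICS:
            raise ConfigurationError(f"dynamics must be one of {DYNAMICS}")
        for f in ("lambda_covariates", "gamma_covariates",
                  "omega_covariates", "p_covariates"):
            object.__setattr__(self, f, tuple(getattr(self, f)))

    def replace(self, **kw) -> "ModelSpec":
        return dataclasses.replace(self, **kw)

    def resolve_K(self, data: CountData) -> int:
        """Default truncation bound: max observed count + 20."""
        K = self.K if self.K is not None else data.max_count + 20
        if K < data.max_count:
            raise ConfigurationError(
                f"K={K} below the maximum observed count {data.max_count}")
        return int(K)


@dataclass
class ParameterVector:
    """Link-scale coefficients, packed into one free vector for optimisation.

    Blocks appear in the order: initial abundance (log link), zero-inflation
    logit (ZIP only), log dispersion (negative binomial only), recruitment
    (log link), apparent survival (logit link), detection (logit link).
    ``pack(unpack(theta)) == theta`` exactly.
    """

    beta_lambda: np.ndarray
    beta_gamma: np.ndarray
    beta_omega: np.ndarray
    beta_p: np.ndarray
    psi_logit: float | None = None    # zip only
    log_alpha: float | None = None    # negbin only

    def pack(self) -> np.ndarray:
        extras = [x for x in (self.psi_logit, self.log_alpha) if x is not None]
        return np.concatenate([np.atleast_1d(np.asarray(b, dtype=float))
                               for b in (self.beta_lambda, extras,
                                         self.beta_gamma, self.beta_omega,
                                         self.beta_p) if len(np.atleast_1d(b))])


@dataclass
class ParameterLayout:
    """Block sizes and names implied by a ModelSpec and its covariates."""

    spec: ModelSpec
    names: list

    @classmethod
    def for_spec(cls, spec: ModelSpec) -> "ParameterLayout":
        names = ["lambda:(Intercept)"]
        names += [f"lambda:{c}" for c in spec.lambda_covariates]
        if spec.initial_family == "zip":
            names.append("psi(logit)")
        elif spec.initial_family == "negbin":
            names.append("alpha(log)")
        names.append("gamma:(Intercept)")
        names += [f"gamma:{c}" for c in spec.gamma_covariates]
        names.append("omega:(Intercept)")
        names += [f"omega:{c}" for c in spec.omega_covariates]
        names.append("p:(Intercept)")
        names += [f"p:{c}" for c in spec.p_covariates]
        return cls(spec, names)

    @property
    def n_params(self) -> int:
        return len(self.names)

    def unpack(self, theta: np.ndarray) -> ParameterVector:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ConfigurationError(
                f"expected {self.n_params} parameters, got {theta.shape}")
        spec = self.spec
        k = 1 + len(spec.lambda_covariates)
        beta_lambda, pos = theta[:k], k
        psi_logit = log_alpha = None
        if spec.initial_family == "zip":
            psi_logit, pos = float(theta[pos]), pos + 1
        elif spec.initial_family == "negbin":
            log_alpha, pos = float(theta[pos]), pos + 1
        k = 1 + len(spec.gamma_covariates)
        beta_gamma, pos = theta[pos:pos + k], pos + k
        k = 1 + len(spec.omega_covariates)
        beta_omega, pos = theta[pos:pos + k], pos + k
        beta_p = theta[pos:]
        return ParameterVector(beta_lambda, beta_gamma, beta_omega, beta_p,
                               psi_logit=psi_logit, log_alpha=log_alpha)


@dataclass
class FitResult:
    """Maximum-likelihood fit with Wald inference.

    ``converged`` is False when the optimiser did not report success or the
    numerically differentiated Hessian is not positive definite; in the
    latter case standard errors are NaN (never silently zeroed).
    """

    spec: ModelSpec
    layout: ParameterLayout
    params: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    nll: float
    n_obs: int
    converged: bool
    hessian_pd: bool
    K: int
    standardization: dict = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)

    Z975 = 1.959964

    @property
    def theta_hat(self) -> ParameterVector:
        return self.layout.unpack(self.params)

    @property
    def names(self) -> list:
        return self.layout.names

    @property
    def n_params(self) -> int:
        return self.layout.n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.nll + 2.0 * self.n_params

    @property
    def aicc(self) -> float:
        k, n = self.n_params, self.n_obs
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def ci95(self) -> np.ndarray:
        half = self.Z975 * self.se
        return np.column_stack([self.params - half, self.params + half])

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def coef_ci(self, name: str) -> tuple:
        lo, hi = self.ci95[self.names.index(name)]
        return float(lo), float(hi)

    def coef_table(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame({"parameter": self.names, "estimate": self.params,
                             "se": self.se, "lcl": ci[:, 0], "ucl": ci[:, 1]})

    def to_dict(self) -> dict:
        def clean(x):
            return np.where(np.isfinite(x), x, None).tolist()
        return {
            "spec": {"initial_family": self.spec.initial_family,
                     "dynamics": self.spec.dynamics,
                     "lambda_covariates": list(self.spec.lambda_covariates),
                     "gamma_covariates": list(self.spec.gamma_covariates),
                     "omega_covariates": list(self.spec.omega_covariates),
                     "p_covariates": list(self.spec.p_covariates),
                     "K": self.K},
            "names": self.names,
            "estimates": clean(self.params),
            "se": clean(self.se),
            "vcov": clean(self.vcov),
            "nll": self.nll, "aic": self.aic, "aicc": self.aicc,
            "n_params": self.n_params, "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "hessian_pd": bool(self.hessian_pd),
            "standardization": {k: list(v)
                                for k, v in self.standardization.items()},
        }
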