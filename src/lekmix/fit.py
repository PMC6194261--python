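"""Maximum-likelihood fitting and Wald inference for N-mixture models."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess3

from .likelihood import NMixtureLikelihood
from .types import (CountData, CovariateTable, FitError, FitResult, ModelSpec,
                    ConfigurationError)

__all__ = ["fit", "predict_effect", "truncation_check", "FitOptions"]

_BIG = 1e12   # objective value substituted for non-finite evaluations


@dataclass
class FitOptions:
    """Optimiser controls.

    starts: 1 deterministic start plus ``starts - 1`` seeded jittered
    restarts; the best optimum is kept.  ``tol`` is the projected-gradient
    tolerance handed to the quasi-Newton optimiser.
    """

    starts: int = 3
    tol: float = 1e-8
    ftol: float = 1e-9      # relative, on the per-observation objective
    max_iter: int = 500
    seed: int = 0
    jitter_sd: float = 0.5
    compute_se: bool = True
    start_values: np.ndarray | None = None   # override the default start


def _default_start(ctx: NMixtureLikelihood) -> np.ndarray:
    """Deterministic moment-flavoured start: slopes 0, intercepts crude."""
    data = ctx.data
    with np.errstate(all="ignore"):
        mean_count = float(np.nanmean(data.counts))
    if not np.isfinite(mean_count):
        mean_count = 0.0
    p0 = 0.5
    lam0 = max(mean_count / p0, 0.25)
    x = np.zeros(ctx.layout.n_params)
    names = ctx.layout.names
    x[names.index("lambda:(Intercept)")] = np.log(lam0)
    x[names.index("omega:(Intercept)")] = 0.85          # logit^-1 ~ 0.70
    if ctx.spec.dynamics == "autoregressive":
        x[names.index("gamma:(Intercept)")] = np.log(0.3)
    else:
        x[names.index("gamma:(Intercept)")] = np.log(max(mean_count, 0.5))
    if "psi(logit)" in names:
        x[names.index("psi(logit)")] = -1.4             # psi ~ 0.2
    if "alpha(log)" in names:
        x[names.index("alpha(log)")] = np.log(2.0)
    # p:(Intercept) starts at logit(0.5) = 0
    return x


def fit(data: CountData, covs: CovariateTable | None, spec: ModelSpec,
        options: FitOptions | None = None, **kw) -> FitResult:
    """Fit one open-population N-mixture model by maximum likelihood.

    Quasi-Newton (L-BFGS-B) optimisation from a deterministic default start
    plus seeded jittered restarts; standard errors come from the inverse of
    a numerically differentiated Hessian.  Keyword arguments override
    individual :class:`FitOptions` fields.
    """
    opts = options or FitOptions()
    if kw:
        opts = FitOptions(**{**opts.__dict__, **kw})
    ctx = NMixtureLikelihood(data, covs, spec)
    _warn_constant_columns(ctx)

    def objective(x):
        try:
            v = ctx.nll(x)
        except FloatingPointError:
            return _BIG
        return v if np.isfinite(v) else _BIG

    # optimise the per-observation mean so gradients are O(1) and the
    # unit initial Hessian guess of the quasi-Newton update is sensible
    scale = max(data.n_observations, 1)

    def objective_scaled(x):
        return objective(x) / scale

    x0 = _default_start(ctx) if opts.start_values is None \
        else np.asarray(opts.start_values, dtype=float)
    rng = np.random.default_rng(opts.seed)
    results = []
    for k in range(max(opts.starts, 1)):
        start = x0 if k == 0 else x0 + rng.normal(0.0, opts.jitter_sd,
                                                  size=x0.shape)
        try:
            res = minimize(objective_scaled, start, method="L-BFGS-B",
                           options={"maxiter": opts.max_iter,
                                    "ftol": opts.ftol, "gtol": opts.tol})
        except Exception:       # noqa: BLE001 - a start may fail outright
            continue
        if np.isfinite(res.fun) and res.fun < _BIG / (2 * scale):
            results.append(res)
    if not results:
        raise FitError(f"all {opts.starts} optimisation starts failed "
                       f"for spec {spec}")
    best = min(results, key=lambda r: r.fun)
    best_nll = float(best.fun) * scale

    n = ctx.layout.n_params
    se = np.full(n, np.nan)
    vcov = np.full((n, n), np.nan)
    hessian_pd = False
    if opts.compute_se:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                H = approx_hess3(best.x, objective)
                np.linalg.cholesky(H)           # raises if not PD
                vcov = np.linalg.inv(H)
                se = np.sqrt(np.diag(vcov))
                hessian_pd = True
            except np.linalg.LinAlgError:
                pass
    converged = bool(best.success) and (hessian_pd or not opts.compute_se)
    return FitResult(spec=spec, layout=ctx.layout, params=best.x,
                     se=se, vcov=vcov, nll=best_nll,
                     n_obs=data.n_observations, converged=converged,
                     hessian_pd=hessian_pd, K=ctx.K,
                     standardization=dict(ctx.standardization),
                     optimizer={"n_starts": len(results),
                                "success": bool(best.success),
                                "message": str(best.message),
                                "n_iter": int(best.nit)})


def _warn_constant_columns(ctx: NMixtureLikelihood) -> None:
    # _zscore already warns for constant covariates while building designs;
    # here we only check the detection design rank as an identifiability hint
    X = ctx.Xp
    if X.shape[0] and np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("detection design is rank deficient", stacklevel=3)


def truncation_check(fitres: FitResult, data: CountData,
                     covs: CovariateTable | None, delta_K: int = 10) -> float:
    """|NLL(K) - NLL(K + delta_K)| at the fitted parameters.

    A value near zero confirms the truncation bound leaves no posterior
    mass above K (guards boom-year tails).
    """
    ctx2 = NMixtureLikelihood(data, covs,
                              fitres.spec.replace(K=fitres.K + delta_K))
    return abs(fitres.nll - ctx2.nll(fitres.params))


_LINKS = {
    "lambda": (np.exp, "log"),
    "gamma": (np.exp, "log"),
    "omega": (expit, "logit"),
    "p": (expit, "logit"),
}


def predict_effect(fitres: FitResult, parameter: str, covariate: str,
                   grid, standardized: bool = False) -> pd.DataFrame:
    """Response-scale effect curve with delta-method 95% CI.

    ``grid`` is on the covariate's original measurement scale unless
    ``standardized=True``; it is transformed internally with the
    standardization constants stored at fit time.  Confidence bounds are
    computed on the link scale and back-transformed, so probability-scale
    curves (omega, p) stay inside [0, 1].
    """
    if parameter not in _LINKS:
        raise ConfigurationError(f"unknown parameter block {parameter!r}")
    inv_link, _ = _LINKS[parameter]
    names = fitres.names
    icol = f"{parameter}:(Intercept)"
    scol = f"{parameter}:{covariate}"
    if scol not in names:
        raise ConfigurationError(
            f"covariate {covariate!r} is not in the fitted {parameter} model")
    grid = np.asarray(grid, dtype=float)
    if standardized:
        z = grid
    else:
        mean, sd = fitres.standardization[scol]
        z = (grid - mean) / sd
    ii, ss = names.index(icol), names.index(scol)
    eta = fitres.params[ii] + fitres.params[ss] * z
    v = (fitres.vcov[ii, ii] + z ** 2 * fitres.vcov[ss, ss]
         + 2.0 * z * fitres.vcov[ii, ss])
    half = FitResult.Z975 * np.sqrt(np.maximum(v, 0.0))
    return pd.DataFrame({
        "x": grid, "z": z,
        "fit": inv_link(eta),
        "lo95": inv_link(eta - half),
        "hi95": inv_link(eta + half),
    })
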