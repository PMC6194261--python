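"""Open-population N-mixture likelihood (Dail–Madsen type model).

Latent lek abundance N_it lives on the truncated grid {0, ..., K}.  The
first season draws N_i1 from an initial mixture (Poisson, zero-inflated
Poisson, or negative binomial with mean lambda_i); subsequent seasons follow

    N_it = S_it + G_it,
    S_it ~ Binomial(N_i,t-1, omega_it)          (apparent survival)
    G_it ~ Poisson(gamma_it)                    (constant dynamics)
    G_it ~ Poisson(gamma_it * N_i,t-1)          (autoregressive dynamics)

and each visit j yields y_itj ~ Binomial(N_it, p_itj).  The marginal
likelihood integrates N out with a forward (filtering) recursion over the
latent grid; all mass above K is folded into state K so every transition
row sums to one exactly.

Numerics: detection terms are assembled on the log scale and the forward
recursion rescales (shifts by the running maximum before exponentiating)
at every season, which is the standard stable evaluation of a log-sum-exp
chain without forming (K+1)^2 logarithm tables at each step.

Covariates are z-scored before entering the linear predictors and the
constants are stored for back-transformation.  Year-level demographic
covariates are standardized over the transition seasons (years 2..T);
"same year" means the covariate measured in the season being transitioned
into, and ``*_lag1`` columns carry the previous year's value.
"""
from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit, gammaln, pdtrc, xlogy

from .types import (ConfigurationError, CountData, CovariateTable, DataError,
                    ModelSpec, ParameterLayout, ParameterVector,
                    DETECTION_COVARIATES)

__all__ = ["build_transition", "transition_matrix", "initial_pmf",
           "detection_loglik", "NMixtureLikelihood", "site_loglik", "nll"]

_LOGCHOOSE_CACHE: dict = {}

try:                                    # optional acceleration
    from numba import njit

    @njit(cache=False)
    def _convolve_sr(B, R, Q):
        """Q[m,a,b] += sum_s B[m,a,s] * R[m,ar,b-s]; R may broadcast a."""
        n, K1, _ = B.shape
        shared = R.shape[1] == 1
        for m in range(n):
            for a in range(K1):
                ra = R[m, 0] if shared else R[m, a]
                for s in range(a + 1):
                    w = B[m, a, s]
                    if w == 0.0:
                        continue
                    for t in range(K1 - s):
                        Q[m, a, s + t] += w * ra[t]

    _HAVE_NUMBA = True
except Exception:                       # pragma: no cover - numba optional
    _HAVE_NUMBA = False


def _log_choose(K: int) -> np.ndarray:
    """(K+1, K+1) table of log C(a, s); -inf where s > a."""
    if K not in _LOGCHOOSE_CACHE:
        a = np.arange(K + 1, dtype=float)
        s = a[None, :]
        with np.errstate(invalid="ignore"):
            tab = (gammaln(a[:, None] + 1) - gammaln(s + 1)
                   - gammaln(a[:, None] - s + 1))
        tab[s > a[:, None]] = -np.inf
        _LOGCHOOSE_CACHE[K] = tab
    return _LOGCHOOSE_CACHE[K]


def _binom_pmf_matrix(omega: np.ndarray, K: int) -> np.ndarray:
    """B[n, a, s] = Binomial(s; a, omega_n) on the (K+1)x(K+1) grid."""
    omega = np.asarray(omega, dtype=float)[:, None, None]
    a = np.arange(K + 1, dtype=float)[None, :, None]
    s = np.arange(K + 1, dtype=float)[None, None, :]
    with np.errstate(invalid="ignore"):
        logb = (_log_choose(K)[None] + xlogy(s, omega)
                + xlogy(a - s, 1.0 - omega))
        B = np.exp(logb)
    B[np.broadcast_to(s > a, B.shape)] = 0.0
    return B


def transition_matrix(omega, gamma, dynamics: str, K: int) -> np.ndarray:
    """Stack of (K+1, K+1) transition kernels, one per (omega, gamma) pair.

    Entry [a, b] is P(N_t = b | N_{t-1} = a): the convolution of a
    Binomial(a, omega) number of survivors with a Poisson number of
    recruits whose rate is gamma (constant dynamics) or gamma * a
    (autoregressive).  The upper tail is folded into state K so each row
    sums to one exactly.
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if dynamics not in ("constant", "autoregressive"):
        raise ConfigurationError(f"unknown dynamics {dynamics!r}")
    if (not np.all(np.isfinite(omega)) or not np.all(np.isfinite(gamma))
            or np.any(omega < 0) or np.any(omega > 1) or np.any(gamma < 0)):
        raise DataError("omega must lie in [0, 1] and gamma must be >= 0")
    n = len(omega)
    B = _binom_pmf_matrix(omega, K)                       # (n, K+1, K+1)
    m = np.arange(K + 1, dtype=float)
    if dynamics == "constant":
        rate = gamma[:, None]                 # same recruit rate for every a
    else:
        rate = gamma[:, None] * np.arange(K + 1, dtype=float)[None, :]
    logR = xlogy(m[None, None, :], rate[:, :, None]) - rate[:, :, None] \
        - gammaln(m + 1)[None, None, :]
    R = np.exp(logR)                                      # (n, a?, K+1)
    # exact convolution: survivors s contribute to columns b >= s.  (An FFT
    # convolution would be faster for large K but rounds the smallest
    # transition probabilities to zero, which puts cliffs in the
    # log-likelihood.)
    Q = np.zeros((n, K + 1, K + 1))
    if _HAVE_NUMBA:
        _convolve_sr(B, np.ascontiguousarray(R), Q)
    else:
        for s in range(K + 1):
            Q[:, :, s:] += B[:, :, s:s + 1] * R[:, :, :K + 1 - s]
    # fold the truncated upper tail into state K via the Poisson survival
    # function; computing it as 1 - rowsum would leave discontinuous
    # cancellation noise in the smallest tail masses.  sf(k) is assembled
    # as a backward cumsum of the pmf grid (all-positive, no cancellation)
    # plus the beyond-grid tail P(G > K).
    S = np.cumsum(R[..., ::-1], axis=-1)[..., ::-1]       # S[m] = P(m<=G<=K)
    tailK = pdtrc(K, rate)                                # P(G > K)
    sfmat = S[..., 1:][..., ::-1] + tailK[..., None]      # sf(K-1-s), s=0..K-1
    sfmat = np.broadcast_to(sfmat, (n, K + 1, K))
    Q[:, :, K] = (B[:, :, :K] * sfmat).sum(axis=2) + B[:, :, K]
    return Q


def build_transition(omega: float, gamma: float, dynamics: str,
                     prev_state: int, K: int) -> np.ndarray:
    """One row of the latent transition kernel, P(N_t = . | N_{t-1} = a)."""
    if not 0 <= prev_state <= K:
        raise DataError(f"prev_state must lie in [0, {K}]")
    return transition_matrix(omega, gamma, dynamics, K)[0, prev_state]


def initial_pmf(family: str, lam, psi=None, alpha=None, K: int = 50,
                ) -> np.ndarray:
    """First-season abundance pmf on {0..K}, upper tail folded into K.

    Families: ``poisson``; ``zip`` with P(0) = psi + (1-psi) e^{-lam};
    ``negbin`` parameterised by mean lam and dispersion alpha
    (variance lam + lam^2 / alpha).
    """
    scalar = np.ndim(lam) == 0
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        raise DataError("lambda must be positive and finite")
    n = np.arange(K + 1)
    if family == "poisson":
        pmf = stats.poisson.pmf(n[None, :], lam[:, None])
        pmf[:, K] = stats.poisson.sf(K - 1, lam)
    elif family == "zip":
        if psi is None:
            raise ConfigurationError("zip family requires psi")
        psi = float(psi)
        if not 0.0 <= psi <= 1.0:
            raise DataError("psi must lie in [0, 1]")
        pmf = (1.0 - psi) * stats.poisson.pmf(n[None, :], lam[:, None])
        pmf[:, K] = (1.0 - psi) * stats.poisson.sf(K - 1, lam)
        pmf[:, 0] += psi
    elif family == "negbin":
        if alpha is None:
            raise ConfigurationError("negbin family requires alpha")
        alpha = float(alpha)
        if not np.isfinite(alpha) or alpha <= 0:
            raise DataError("alpha must be positive and finite")
        pnb = alpha / (alpha + lam)
        pmf = stats.nbinom.pmf(n[None, :], alpha, pnb[:, None])
        pmf[:, K] = stats.nbinom.sf(K - 1, alpha, pnb)
    else:
        raise ConfigurationError(f"unknown family {family!r}")
    return pmf[0] if scalar else pmf


def detection_loglik(counts_at_it, N: int, p_vec) -> float:
    """log P(y_1..J | N) = sum_j log Binomial(y_j; N, p_j).

    Missing visits (NaN) are skipped; a season with no visits contributes 0
    (a vacuous observation).  Returns -inf when any count exceeds N.
    """
    y = np.asarray(counts_at_it, dtype=float)
    p = np.asarray(p_vec, dtype=float)
    keep = ~np.isnan(y)
    y, p = y[keep], p[keep]
    if y.size == 0:
        return 0.0
    if np.any(y < 0):
        raise DataError("negative counts are not allowed")
    if np.any(y > N):
        return -np.inf
    lp = (_log_choose(int(max(N, y.max())))[N, y.astype(int)]
          + xlogy(y, p) + xlogy(N - y, 1.0 - p))
    return float(lp.sum())


def _zscore(values: np.ndarray, name: str) -> tuple:
    """Z-score ignoring NaN; constant columns fall back to centering."""
    mean = float(np.nanmean(values))
    sd = float(np.nanstd(values))
    if not np.isfinite(sd) or sd == 0.0:
        import warnings
        warnings.warn(f"covariate {name!r} is constant after standardization",
                      stacklevel=3)
        sd = 1.0
    z = (values - mean) / sd
    return np.where(np.isnan(z), 0.0, z), (mean, sd)


class NMixtureLikelihood:
    """Pre-assembled likelihood context for one (data, covariates, spec).

    Builds the z-scored design matrices, the visit index arrays, and the
    parameter layout once; :meth:`nll` is then cheap enough to sit inside a
    quasi-Newton loop.
    """

    def __init__(self, data: CountData, covs: CovariateTable | None,
                 spec: ModelSpec):
        covs = covs if covs is not None else CovariateTable()
        self.data, self.covs, self.spec = data, covs, spec
        self.K = spec.resolve_K(data)
        self.layout = ParameterLayout.for_spec(spec)
        self.standardization: dict = {}
        M, T = data.M, data.T
        self._grid = np.arange(self.K + 1, dtype=float)

        # ---- visit-level bookkeeping for the detection model
        obs = ~np.isnan(data.counts)
        self.vis_i, self.vis_t, self.vis_j = np.nonzero(obs)
        self.y_vis = data.counts[obs].astype(int)
        self.Xp = self._detection_design()
        self._logC = _log_choose(self.K)
        self._invalid = self._grid[None, :] < self.y_vis[:, None]
        # visit rows from np.nonzero are sorted by (site, season): contiguous
        # segments let the per-cell detection sums use reduceat
        cell = self.vis_i * T + self.vis_t
        self._seg_starts = np.flatnonzero(
            np.r_[True, np.diff(cell) != 0]) if cell.size else np.array([], int)
        self._seg_cells = cell[self._seg_starts] if cell.size else cell
        # constant pieces of the per-visit binomial log-pmf
        self._logC_rows = self._logC.T[self.y_vis]
        self._n_minus_y = self._grid[None, :] - self.y_vis[:, None]

        # small memo tables per parameter block: finite-difference gradient
        # steps perturb one coordinate, so the other blocks' matrices can
        # be reused verbatim
        self._memo: dict = {"D": {}, "F": {}, "Q": {}}

        # ---- site-level design for initial abundance
        self.Xlam = self._block_design_site(spec.lambda_covariates, "lambda")

        # ---- transition designs, years 2..T (value of the year entered)
        self.Xgam = self._block_design_transition(spec.gamma_covariates,
                                                  "gamma")
        self.Xom = self._block_design_transition(spec.omega_covariates,
                                                 "omega")
        # transitions are shared across sites unless a lek-level covariate
        # (e.g. cow days/ha) enters gamma or omega
        self._site_varying = (self.Xgam.shape[0] > 1 or self.Xom.shape[0] > 1)

    # ------------------------------------------------------------------
    def _detection_design(self) -> np.ndarray:
        nv = len(self.y_vis)
        cols = [np.ones(nv)]
        for name in self.spec.p_covariates:
            if name == "daily_rain":
                raw = self.data.visit_rain[self.vis_i, self.vis_t, self.vis_j]
            elif name == "daily_tmax":
                raw = self.data.visit_tmax[self.vis_i, self.vis_t, self.vis_j]
            elif name == "effort":
                raw = self.data.effort[self.vis_i, self.vis_t].astype(float)
            elif name in self.covs.site_year:
                raw = self.covs.site_year[name][self.vis_i, self.vis_t]
            else:
                raise ConfigurationError(
                    f"unknown detection covariate {name!r}; expected one of "
                    f"{DETECTION_COVARIATES}")
            z, const = _zscore(raw, name)
            self.standardization[f"p:{name}"] = const
            cols.append(z)
        return np.column_stack(cols)

    def _block_design_site(self, names, block) -> np.ndarray:
        M = self.data.M
        cols = [np.ones(M)]
        for name in names:
            if name in self.covs.site:
                raw = np.asarray(self.covs.site[name], dtype=float)
            else:
                raise ConfigurationError(
                    f"unknown site covariate {name!r} on {block}")
            z, const = _zscore(raw, name)
            self.standardization[f"{block}:{name}"] = const
            cols.append(z)
        return np.column_stack(cols)

    def _block_design_transition(self, names, block) -> np.ndarray:
        """(Ms, T-1, k) design; Ms == 1 when nothing varies by site."""
        T = self.data.T
        years_in = self.data.years[1:]
        site_varying = any(n in self.covs.site_year for n in names)
        Ms = self.data.M if site_varying else 1
        cols = [np.ones((Ms, T - 1))]
        for name in names:
            if name in self.covs.site_year:
                raw = np.asarray(self.covs.site_year[name],
                                 dtype=float)[:, 1:]
            elif self.covs.year is not None and name in self.covs.year.columns:
                raw = np.broadcast_to(
                    self.covs.year_values(name, years_in)[None, :],
                    (Ms, T - 1)).copy()
            else:
                raise ConfigurationError(
                    f"unknown demographic covariate {name!r} on {block}")
            z, const = _zscore(raw, name)
            self.standardization[f"{block}:{name}"] = const
            cols.append(np.broadcast_to(z, (Ms, T - 1)))
        return np.stack(cols, axis=2)

    # ------------------------------------------------------------------
    def unpack(self, theta) -> ParameterVector:
        return self.layout.unpack(theta)

    def _memoized(self, which: str, key_arrays, build):
        memo = self._memo[which]
        key = b"".join(np.asarray(a, dtype=float).tobytes()
                       for a in key_arrays if a is not None)
        if key not in memo:
            if len(memo) > 16:
                memo.clear()
            memo[key] = build()
        return memo[key]

    def _detection_logmat(self, beta_p) -> np.ndarray:
        """(M, T, K+1) sum of visit log-binomial terms; 0 when no visits."""
        M, T = self.data.M, self.data.T
        D = np.zeros((M, T, self.K + 1))
        if len(self.y_vis) == 0:
            return D
        p = np.clip(expit(self.Xp @ beta_p), 1e-12, 1.0 - 1e-12)
        y = self.y_vis.astype(float)
        L = (self._logC_rows + xlogy(y, p)[:, None]
             + self._n_minus_y * np.log1p(-p)[:, None])
        L[self._invalid] = -np.inf
        sums = np.add.reduceat(L, self._seg_starts, axis=0)
        D.reshape(M * T, self.K + 1)[self._seg_cells] = sums
        return D

    def _initial_matrix(self, pv: ParameterVector) -> np.ndarray:
        # linear predictors are clamped so extreme optimizer excursions
        # degrade the likelihood smoothly instead of overflowing
        lam = np.exp(np.clip(self.Xlam @ pv.beta_lambda, -40.0, 40.0))
        psi = expit(pv.psi_logit) if pv.psi_logit is not None else None
        alpha = np.exp(np.clip(pv.log_alpha, -40.0, 40.0)) \
            if pv.log_alpha is not None else None
        F = initial_pmf(self.spec.initial_family, lam, psi=psi, alpha=alpha,
                        K=self.K)
        return F if F.ndim == 2 else F[None, :]

    def _transition_stack(self, pv: ParameterVector):
        """List over t=1..T-1 of (Q, site_index | None)."""
        gam = np.exp(np.clip(np.einsum("mtk,k->mt", self.Xgam,
                                       pv.beta_gamma), -40.0, 40.0))
        om = expit(np.einsum("mtk,k->mt", self.Xom, pv.beta_omega))
        Ms = max(gam.shape[0], om.shape[0])
        gam = np.broadcast_to(gam, (Ms, gam.shape[1]))
        om = np.broadcast_to(om, (Ms, om.shape[1]))
        # one batched kernel build over all distinct (omega, gamma) pairs
        pairs = np.column_stack([om.ravel(), gam.ravel()])
        uniq, inverse = np.unique(pairs.round(12), axis=0,
                                  return_inverse=True)
        Qu = transition_matrix(uniq[:, 0], uniq[:, 1], self.spec.dynamics,
                               self.K)
        inverse = inverse.reshape(Ms, -1)
        out = []
        for t in range(self.data.T - 1):
            if Ms == 1:
                out.append((Qu[inverse[0, t]], None))
            else:
                out.append((Qu, inverse[:, t]))
        return out

    # ------------------------------------------------------------------
    def site_loglik_vector(self, theta) -> np.ndarray:
        """Marginal log-likelihood contribution of every site (forward pass)."""
        pv = self.unpack(theta)
        if not np.all(np.isfinite(np.asarray(theta, dtype=float))):
            raise DataError("non-finite parameter vector")
        D = self._memoized("D", [pv.beta_p],
                           lambda: self._detection_logmat(pv.beta_p))
        F = self._memoized("F", [pv.beta_lambda, pv.psi_logit, pv.log_alpha],
                           lambda: self._initial_matrix(pv))
        M, T = self.data.M, self.data.T
        trans = self._memoized("Q", [pv.beta_gamma, pv.beta_omega],
                               lambda: self._transition_stack(pv))
        lls = np.zeros(M)
        shift = D[:, 0, :].max(axis=1)
        A = np.broadcast_to(F, (M, self.K + 1)) * np.exp(
            D[:, 0, :] - shift[:, None])
        # the running sum is floored at the smallest normal double so a
        # parameter region that annihilates all forward mass yields a very
        # large but finite and smoothly decreasing objective (a hard -inf
        # wall breaks quasi-Newton line searches)
        floor = 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            s = A.sum(axis=1)
            lls += shift + np.log(np.maximum(s, floor))
            A = np.where(s[:, None] > 0, A / s[:, None], 0.0)
            for t in range(1, T):
                Q, idx = trans[t - 1]
                A = A @ Q if idx is None else np.einsum(
                    "mk,mkn->mn", A, Q[idx])
                shift = D[:, t, :].max(axis=1)
                A = A * np.exp(D[:, t, :] - shift[:, None])
                s = A.sum(axis=1)
                lls += shift + np.log(np.maximum(s, floor))
                A = np.where(s[:, None] > 0, A / s[:, None], 0.0)
        return lls

    def nll(self, theta) -> float:
        """Negative total log-likelihood (the optimisation objective)."""
        return float(-np.sum(self.site_loglik_vector(theta)))

    # ------------------------------------------------------------------
    def posterior_latent(self, theta) -> np.ndarray:
        """(M, T, K+1) empirical-Bayes posterior P(N_it = n | all counts_i).

        Forward-backward smoothing at the supplied parameter values; every
        season is conditioned on the full count history of its site.
        """
        pv = self.unpack(theta)
        D = self._detection_logmat(pv.beta_p)
        F = self._initial_matrix(pv)
        M, T, Kp = self.data.M, self.data.T, self.K + 1
        trans = self._transition_stack(pv)
        E = np.exp(D - D.max(axis=2, keepdims=True))        # (M, T, K+1)
        alpha = np.zeros((M, T, Kp))
        A = np.broadcast_to(F, (M, Kp)) * E[:, 0, :]
        A = A / np.maximum(A.sum(axis=1, keepdims=True), 1e-300)
        alpha[:, 0] = A
        for t in range(1, T):
            Q, idx = trans[t - 1]
            A = A @ Q if idx is None else np.einsum("mk,mkn->mn", A, Q[idx])
            A = A * E[:, t, :]
            A = A / np.maximum(A.sum(axis=1, keepdims=True), 1e-300)
            alpha[:, t] = A
        beta = np.ones((M, Kp))
        post = np.zeros((M, T, Kp))
        post[:, T - 1] = alpha[:, T - 1]
        for t in range(T - 2, -1, -1):
            Q, idx = trans[t]
            v = E[:, t + 1, :] * beta
            beta = v @ Q.T if idx is None else np.einsum(
                "mn,mkn->mk", v, Q[idx])
            beta = beta / np.maximum(beta.max(axis=1, keepdims=True), 1e-300)
            w = alpha[:, t] * beta
            post[:, t] = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
        return post


def site_loglik(data: CountData, covs: CovariateTable | None,
                theta, spec: ModelSpec) -> np.ndarray:
    """Per-site forward log-likelihoods for packed link-scale ``theta``."""
    return NMixtureLikelihood(data, covs, spec).site_loglik_vector(theta)


def nll(theta, data: CountData, covs: CovariateTable | None,
        spec: ModelSpec) -> float:
    """Objective wrapper: -sum of site log-likelihoods."""
    return NMixtureLikelihood(data, covs, spec).nll(theta)
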