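"""Independent brute-force oracles for the likelihood tests.

Everything here is written directly from the model definition using scipy
distribution objects and explicit sums over latent states/trajectories; it
deliberately shares no code with the forward-recursion implementation.
"""
import itertools

import numpy as np
from scipy import stats


def initial_pmf_oracle(family, lam, psi, alpha, K):
    n = np.arange(K + 1)
    if family == "poisson":
        pmf = stats.poisson.pmf(n, lam)
        pmf[K] = stats.poisson.sf(K - 1, lam)
    elif family == "zip":
        pmf = (1 - psi) * stats.poisson.pmf(n, lam)
        pmf[K] = (1 - psi) * stats.poisson.sf(K - 1, lam)
        pmf[0] += psi
    elif family == "negbin":
        p = alpha / (alpha + lam)
        pmf = stats.nbinom.pmf(n, alpha, p)
        pmf[K] = stats.nbinom.sf(K - 1, alpha, p)
    else:
        raise ValueError(family)
    return pmf


def transition_row_oracle(omega, gamma, dynamics, a, K):
    """Survivor-recruit convolution, summed term by term."""
    rate = gamma * a if dynamics == "autoregressive" else gamma
    row = np.zeros(K + 1)
    for b in range(K):
        row[b] = sum(stats.binom.pmf(s, a, omega)
                     * stats.poisson.pmf(b - s, rate)
                     for s in range(min(a, b) + 1))
    row[K] = sum(stats.binom.pmf(s, a, omega)
                 * stats.poisson.sf(K - 1 - s, rate)
                 for s in range(a + 1))
    return row


def enumeration_loglik(counts_i, p, family, lam, gamma, omega, dynamics, K,
                       psi=None, alpha=None):
    """Site log-likelihood by summing over all (K+1)^T latent trajectories."""
    T = counts_i.shape[0]
    F = initial_pmf_oracle(family, lam, psi, alpha, K)
    Q = np.array([transition_row_oracle(omega, gamma, dynamics, a, K)
                  for a in range(K + 1)])
    states = np.arange(K + 1)
    # detection term per (t, N): product of binomial pmfs over visits
    det = np.ones((T, K + 1))
    for t in range(T):
        ys = counts_i[t][~np.isnan(counts_i[t])]
        for y in ys:
            det[t] *= stats.binom.pmf(y, states, p)
    total = 0.0
    for traj in itertools.product(range(K + 1), repeat=T):
        pr = F[traj[0]] * det[0, traj[0]]
        for t in range(1, T):
            pr *= Q[traj[t - 1], traj[t]] * det[t, traj[t]]
        total += pr
    return np.log(total)


def closed_population_loglik(counts_i, p, family, lam, K,
                             psi=None, alpha=None):
    """Closed N-mixture with one shared N and all visits pooled."""
    F = initial_pmf_oracle(family, lam, psi, alpha, K)
    ys = counts_i[~np.isnan(counts_i)]
    states = np.arange(K + 1)
    det = np.ones(K + 1)
    for y in ys:
        det *= stats.binom.pmf(y, states, p)
    return np.log(np.sum(F * det))


def anova_oracle(group_a, group_b):
    """Textbook one-way ANOVA sums of squares for two groups."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    allv = np.concatenate([a, b])
    grand = allv.mean()
    ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, len(allv) - 2
    msb, msw = ssb / df1, ssw / df2
    F = msb / msw
    return F, df1, df2


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum()
                 / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
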