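"""Shared fixtures: tiny count datasets and small cached simulations."""
import numpy as np
import pytest

from lekmix.types import CountData, CovariateTable, ModelSpec
from lekmix.synthetic import ScenarioConfig, simulate


def make_tiny_data(seed: int, M: int = 2, T: int = 3, J: int = 2,
                   max_count: int = 3, missing: float = 0.2) -> CountData:
    """Small random CountData with some missing visits."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, max_count + 1, (M, T, J)).astype(float)
    counts[rng.random((M, T, J)) < missing] = np.nan
    if np.isnan(counts).all():
        counts[0, 0, 0] = 1.0
    return CountData([f"s{i}" for i in range(M)],
                     np.arange(2004, 2004 + T), counts,
                     np.zeros((M, T, J)), np.zeros((M, T, J)))


@pytest.fixture(scope="session")
def tiny_data():
    return make_tiny_data(seed=7)


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated survey shared across unit tests (not acceptance)."""
    cfg = ScenarioConfig(n_sites=20, n_years=8, seed=424,
                         gamma_covariate="hot_days", gamma_slope=-0.5)
    return simulate(cfg)


@pytest.fixture(scope="session")
def null_spec():
    return ModelSpec()


def base_theta(spec: ModelSpec, lam=2.5, gamma=0.8, omega_logit=0.3,
               p_logit=0.1, psi_logit=-0.5, log_alpha=0.7):
    """Packed intercept-only parameter vector for a covariate-free spec."""
    theta = [np.log(lam)]
    if spec.initial_family == "zip":
        theta.append(psi_logit)
    elif spec.initial_family == "negbin":
        theta.append(log_alpha)
    theta += [np.log(gamma), omega_logit, p_logit]
    return np.array(theta)
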