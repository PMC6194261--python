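"""Four-step model building, candidate menus, weights and the grazing scan."""
import numpy as np
import pandas as pd
import pytest

from lekmix.fit import FitOptions
from lekmix.selection import (Candidate, akaike_weights, annual_weather_menu,
                              full_weather_menu, grazing_scan,
                              seasonal_weather_menu, step1_distribution,
                              step2_screen_detection, step3_initial_abundance,
                              step4_demographic_scan)
from lekmix.synthetic import ScenarioConfig, grazing_scenario, simulate
from lekmix.types import DataError, ModelSpec

FAST = FitOptions(starts=1, compute_se=True)


class TestAkaikeWeights:
    def test_symmetry(self):
        np.testing.assert_allclose(akaike_weights([100.0, 100.0]),
                                   [0.5, 0.5], atol=1e-12)

    def test_closed_form_two_models(self):
        w = akaike_weights([100.0, 102.0])
        e = np.exp(-1.0)
        np.testing.assert_allclose(w, [1 / (1 + e), e / (1 + e)], atol=1e-12)
        np.testing.assert_allclose(w, [0.731, 0.269], atol=5e-4)

    def test_single_model(self):
        np.testing.assert_allclose(akaike_weights([123.4]), [1.0])

    def test_sums_to_one_and_errors(self):
        w = akaike_weights(np.random.default_rng(0).normal(500, 30, 12))
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(DataError):
            akaike_weights([])


class TestMenus:
    def test_annual_menu_is_the_twenty_weather_models(self):
        menu = annual_weather_menu()
        assert len(menu) == 20
        assert len({c.label for c in menu}) == 20
        assert {c.process for c in menu} == {"recruitment", "survival"}
        assert sum(c.period == "year before" for c in menu) == 10

    def test_seasonal_menu_excludes_winter_and_spring_lags(self):
        menu = seasonal_weather_menu()
        lagged = [c for c in menu if c.period == "year before"]
        assert all(c.covariate.endswith(("summer", "fall")) for c in lagged)
        assert len(full_weather_menu()) == len(menu) + 20

    def test_lag_column_naming(self):
        c = Candidate("survival", "pmdi_avg", "year before")
        assert c.column == "pmdi_avg_lag1"


@pytest.fixture(scope="module")
def sim_small():
    cfg = ScenarioConfig(n_sites=20, n_years=8, seed=99,
                         gamma_covariate="hot_days", gamma_slope=-0.8,
                         p_rain_slope=-0.8)
    return simulate(cfg)


def test_step1_prefers_poisson_on_poisson_data():
    """Under a constant-rate Poisson truth the richer families gain no fit,
    so their extra parameter costs them the AIC ranking."""
    sim = simulate(ScenarioConfig(n_sites=25, n_years=6, seed=303))
    res = step1_distribution(sim.data, sim.covs, FAST)
    assert res.family == "poisson"
    t = res.table.set_index("family")
    assert (res.table["dAIC"] >= 0).all()
    assert t.loc["poisson", "aic"] <= t.loc["negbin", "aic"] + 0.1
    assert t.loc["poisson", "aic"] <= t.loc["zip", "aic"] + 0.1


def test_step1_detects_zero_inflation():
    cfg = ScenarioConfig(n_sites=30, n_years=6, initial_family="zip",
                         psi=0.45, lam=10.0, omega=0.9, gamma=0.05,
                         seed=17)
    sim = simulate(cfg)
    res = step1_distribution(sim.data, sim.covs, FAST)
    t = res.table.set_index("family")
    assert t.loc["zip", "aic"] < t.loc["poisson", "aic"] - 2


def test_step2_retains_the_active_detection_covariate(sim_small):
    res = step2_screen_detection(sim_small.data, sim_small.covs, "poisson",
                                 FAST)
    assert "daily_rain" in res.retained
    tab = res.table.set_index("covariate")
    assert bool(tab.loc["daily_rain", "retained"])


def test_step3_retains_informative_prior_count():
    cfg = ScenarioConfig(n_sites=30, n_years=5, lambda_site_sd=0.6,
                         lambda_prior_slope=0.0, seed=5)
    sim = simulate(cfg)
    res = step3_initial_abundance(sim.data, sim.covs, "poisson", (), FAST)
    assert res.retained is True


def test_step3_skips_without_prior_data(sim_small):
    covs = sim_small.covs
    covs2 = type(covs)(covs.year, dict(covs.site_year), {})
    res = step3_initial_abundance(sim_small.data, covs2, "poisson", (), FAST)
    assert res.retained is None and "skip" in res.note


def test_step3_degenerate_prior_counts(sim_small):
    covs = sim_small.covs
    covs2 = type(covs)(covs.year, dict(covs.site_year),
                       {"prior_count": np.full(sim_small.data.M, 4.0)})
    with pytest.warns(UserWarning, match="constant"):
        res = step3_initial_abundance(sim_small.data, covs2, "poisson", (),
                                      FAST)
    assert res.retained is False


class TestStep4:
    @pytest.fixture(scope="class")
    @staticmethod
    def scan(sim_small):
        cands = [Candidate("recruitment", v, per)
                 for v in ("hot_days", "precip")
                 for per in ("same year", "year before")]
        return step4_demographic_scan(sim_small.data, sim_small.covs,
                                      ModelSpec(), "recruitment", cands,
                                      options=FAST)

    def test_truth_ranks_first(self, scan):
        table, _ = scan
        assert table.iloc[0]["covariate"] == "hot_days"
        assert table.iloc[0]["period"] == "same year"
        assert table.iloc[0]["dAIC"] == 0.0

    def test_weights_normalised(self, scan):
        table, _ = scan
        conv = table[table["converged"]]
        assert conv["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert conv["weight_process"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_ranking_invariant_to_candidate_order(self, sim_small, scan):
        table, _ = scan
        cands = [Candidate("recruitment", v, per)
                 for v in ("precip", "hot_days")
                 for per in ("year before", "same year")]
        table2, _ = step4_demographic_scan(sim_small.data, sim_small.covs,
                                           ModelSpec(), "recruitment",
                                           cands, options=FAST)
        assert table["label"].tolist() == table2["label"].tolist()
        np.testing.assert_allclose(table["aic"], table2["aic"], atol=1e-4)

    def test_single_candidate_weight_is_one(self, sim_small):
        table, _ = step4_demographic_scan(
            sim_small.data, sim_small.covs, ModelSpec(), "survival",
            [Candidate("survival", "pmdi_avg", "same year")], options=FAST)
        assert table["weight"].iloc[0] == pytest.approx(1.0)

    def test_process_mismatch_rejected(self, sim_small):
        with pytest.raises(DataError):
            step4_demographic_scan(sim_small.data, sim_small.covs,
                                   ModelSpec(), "survival",
                                   [Candidate("recruitment", "precip",
                                              "same year")], options=FAST)

    def test_dynamics_follow_process(self, scan, sim_small):
        _, fits = scan
        assert all(f.spec.dynamics == "autoregressive"
                   for f in fits.values())
        table, fits_s = step4_demographic_scan(
            sim_small.data, sim_small.covs, ModelSpec(), "survival",
            [Candidate("survival", "precip", "same year")], options=FAST)
        assert all(f.spec.dynamics == "constant" for f in fits_s.values())


class TestGrazingScan:
    def test_predrought_effects_recovered(self):
        sim = simulate(grazing_scenario(seed=2, n_sites=30))
        res = grazing_scan(sim.data, sim.covs, split_year=2011,
                           options=FAST)
        assert set(res) == {"predrought"}
        t = res["predrought"]["table"].set_index("process")
        for proc in ("recruitment", "survival"):
            assert t.loc[proc, "beta"] > 0
            assert t.loc[proc, "lcl"] > 0

    def test_masked_year_reported(self):
        sim = simulate(grazing_scenario(seed=3, period="postdrought",
                                        n_sites=25))
        res = grazing_scan(sim.data, sim.covs, split_year=2011,
                           options=FAST)
        tab = res["postdrought"]["table"]
        assert tab["masked_years"].iloc[0] == [2012]

    def test_all_grazing_missing_is_informative_error(self, sim_small):
        covs = sim_small.covs
        cd = np.full((sim_small.data.M, sim_small.data.T), np.nan)
        covs2 = type(covs)(covs.year, {"cow_days": cd}, dict(covs.site))
        with pytest.raises(DataError, match="predrought"):
            grazing_scan(sim_small.data, covs2, split_year=2020,
                         options=FAST)

    def test_short_period_rejected(self):
        sim = simulate(grazing_scenario(seed=4, n_sites=10))
        with pytest.raises(DataError, match="unidentifiable"):
            grazing_scan(sim.data, sim.covs, split_year=2006, options=FAST)
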