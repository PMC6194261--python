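"""Synthetic survey generator: covariate builders, fixtures and moments."""
import numpy as np
import pandas as pd
import pytest

from lekmix.covariates import (classify_wet_dry, cow_days_per_ha, hot_days,
                               pearson_r, seasonal_aggregate,
                               build_seasonal_table, cow_days_site_year)
from lekmix.synthetic import (ScenarioConfig, drought_scenario, load_table1,
                              simulate)
from lekmix.types import ConfigurationError, DataError

from oracles import pearson_oracle


class TestHotDays:
    def test_none_above_threshold(self):
        assert hot_days(np.full(365, 30.0), 35.0) == 0

    def test_counts_exceedances(self):
        series = np.r_[np.full(100, 20.0), [36.0, 40.0, 35.5]]
        assert hot_days(series, 35.0) == 3

    def test_threshold_is_strict(self):
        assert hot_days([35.0, 35.0, 36.0], 35.0) == 1

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            hot_days([])


class TestCowDays:
    def test_scale_anchor(self):
        # 100 head for 10 days on 500 ha = 2.0 cow days/ha
        assert cow_days_per_ha(100, 10, 500) == pytest.approx(2.0)

    def test_zero_cattle(self):
        assert cow_days_per_ha(0, 55, 700) == 0.0

    def test_rotations_add(self):
        assert cow_days_per_ha([50, 50], [10, 10], [500, 500]) == \
            pytest.approx(2.0)

    def test_bad_area(self):
        with pytest.raises(DataError):
            cow_days_per_ha(10, 5, 0)


class TestSeasonalAggregate:
    @staticmethod
    def _monthly(values_by_year):
        rows = [(y, m, v) for y, vals in values_by_year.items()
                for m, v in zip(range(1, 13), vals)]
        return pd.DataFrame(rows, columns=["year", "month", "value"])

    def test_uniform_rain_gives_3cm_per_season(self):
        monthly = self._monthly({2004: [1.0] * 12, 2005: [1.0] * 12})
        for season in ("winter", "breeding", "summer", "fall"):
            assert seasonal_aggregate(monthly, season, 2005) == \
                pytest.approx(3.0)

    def test_winter_spans_the_year_boundary(self):
        vals = {2004: [0.0] * 11 + [10.0], 2005: [0.0] * 12}
        monthly = self._monthly(vals)
        assert seasonal_aggregate(monthly, "winter", 2005) == \
            pytest.approx(10.0)

    def test_incomplete_season_is_missing(self):
        monthly = self._monthly({2005: [1.0] * 12})   # no Dec 2004
        assert np.isnan(seasonal_aggregate(monthly, "winter", 2005))
        assert seasonal_aggregate(monthly, "summer", 2005) == \
            pytest.approx(3.0)

    def test_mean_mode_for_pmdi(self):
        monthly = self._monthly({2004: list(range(12)),
                                 2005: list(range(12))})
        assert seasonal_aggregate(monthly, "summer", 2005, how="mean") == \
            pytest.approx(6.0)

    def test_lagged_column_shifts_by_one_year(self):
        monthly = self._monthly({2004: [2.0] * 12, 2005: [4.0] * 12,
                                 2006: [6.0] * 12})
        tab = build_seasonal_table(monthly, "value", "sum", "precip")
        lagged = tab["precip_summer"].shift(1)
        assert lagged.loc[2005] == tab["precip_summer"].loc[2004]


class TestWetDry:
    def test_observed_dry_year(self):
        assert classify_wet_dry(20.47) == "dry"        # the drought year

    def test_observed_wet_year(self):
        assert classify_wet_dry(66.09) == "wet"

    def test_boundaries_are_strict(self):
        assert classify_wet_dry(32.0) == "normal"
        assert classify_wet_dry(46.0) == "normal"

    def test_bad_percentiles(self):
        with pytest.raises(DataError):
            classify_wet_dry(40.0, p25=50.0, p75=40.0)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(5.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 1.0, 4.0]
        assert pearson_r(x, y) == pytest.approx(pearson_oracle(x, y),
                                                abs=1e-12)

    def test_pairwise_complete(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 9.0, 8.0, 10.0]
        assert pearson_r(x, y) == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestTable1Fixture:
    def test_twelve_years_and_missing_cells_preserved(self):
        fx = load_table1()
        assert len(fx) == 12
        assert fx["year"].tolist() == list(range(2004, 2016))
        assert np.isnan(fx.set_index("year").loc[2012, "cow_days"])
        assert np.isnan(fx.set_index("year").loc[2004, "cow_days"])
        assert fx.set_index("year").loc[2011, "hot_days"] == 84

    def test_hot_day_extreme_structure(self):
        hd = load_table1().set_index("year")["hot_days"]
        top2 = hd.sort_values().iloc[-2:]
        assert hd.idxmax() == 2011
        assert hd.max() > 1.4 * top2.iloc[0]


class TestSimulate:
    def test_seed_reproducibility_and_divergence(self):
        a = simulate(ScenarioConfig(n_sites=8, n_years=5, seed=1))
        b = simulate(ScenarioConfig(n_sites=8, n_years=5, seed=1))
        c = simulate(ScenarioConfig(n_sites=8, n_years=5, seed=2))
        np.testing.assert_array_equal(a.data.counts, b.data.counts)
        np.testing.assert_array_equal(a.truth["N"], b.truth["N"])
        assert not np.array_equal(a.data.counts, c.data.counts,
                                  equal_nan=True)

    def test_perfect_detection_boundary(self):
        sim = simulate(ScenarioConfig(n_sites=5, n_years=4, p=1.0, seed=3))
        obs = ~np.isnan(sim.data.counts)
        i, t, _ = np.nonzero(obs)
        np.testing.assert_array_equal(sim.data.counts[obs],
                                      sim.truth["N"][i, t])

    def test_frozen_population_when_omega1_gamma0(self):
        sim = simulate(ScenarioConfig(n_sites=6, n_years=5, omega=1.0,
                                      gamma=0.0, seed=4))
        N = sim.truth["N"]
        assert (N == N[:, :1]).all()

    def test_initial_moments_match_family(self):
        """Mean of N_1 ~ lambda within 3 standard errors at large M."""
        sim = simulate(ScenarioConfig(n_sites=5000, n_years=2, lam=8.0,
                                      seed=5))
        n1 = sim.truth["N"][:, 0]
        se = np.sqrt(8.0 / 5000)
        assert abs(n1.mean() - 8.0) < 3 * se
        # Poisson: variance ~ mean
        assert abs(n1.var() / n1.mean() - 1.0) < 0.1

    def test_negbin_overdispersion(self):
        sim = simulate(ScenarioConfig(n_sites=5000, n_years=2,
                                      initial_family="negbin", alpha=2.0,
                                      lam=8.0, seed=6))
        n1 = sim.truth["N"][:, 0]
        # variance = lam + lam^2/alpha = 8 + 32 = 40
        assert n1.var() == pytest.approx(40.0, rel=0.15)

    def test_drought_scenario_count_scale(self):
        """Mean counts fall from ~8 early to ~1-3 late (observed scale)."""
        sim = simulate(drought_scenario(seed=7))
        with np.errstate(all="ignore"):
            by_year = np.nanmean(sim.data.counts, axis=(0, 2))
        assert 3.0 < np.mean(by_year[:3]) < 14.0
        assert 0.2 < np.mean(by_year[-3:]) < 3.0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(p=1.4, seed=0)
        with pytest.raises(ConfigurationError):
            ScenarioConfig(omega=-0.1, seed=0)

    def test_lagged_year_columns_consistent(self):
        sim = simulate(ScenarioConfig(n_sites=5, n_years=6, seed=9))
        tab = sim.covs.year
        for c in ("precip", "hot_days", "pmdi_avg"):
            got = tab[f"{c}_lag1"].iloc[1:]
            want = tab[c].shift(1).iloc[1:]
            np.testing.assert_allclose(got, want)

    def test_grazing_records_reproduce_cow_days(self):
        sim = simulate(ScenarioConfig(n_sites=10, n_years=5, seed=10))
        cd = cow_days_site_year(sim.grazing, sim.data)
        np.testing.assert_allclose(cd, sim.covs.site_year["cow_days"])
        t2012 = np.where(sim.data.years == 2012)[0]
        if t2012.size:
            assert np.isnan(cd[:, t2012[0]]).all()
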