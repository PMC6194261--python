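"""Empirical-Bayes abundance, the pre/post ANOVA and the fold change."""
import numpy as np
import pandas as pd
import pytest

from lekmix.estimates import (AbundanceSeries, anova_pre_post, fold_change,
                              posterior_abundance)
from lekmix.fit import fit
from lekmix.types import (CountData, CovariateTable, DataError, FitError,
                          ModelSpec)
from lekmix.synthetic import ScenarioConfig, simulate

from oracles import anova_oracle


def _series_from_values(years, values):
    """Hand-built AbundanceSeries with prescribed year means."""
    years = np.asarray(years)
    summary = pd.DataFrame({"year": years, "mean": values,
                            "total": np.asarray(values) * 10})
    return AbundanceSeries(pd.DataFrame(), summary, years,
                           np.zeros((1, len(years), 1)))


class TestAnova:
    def test_matches_textbook_sums_of_squares(self):
        series = _series_from_values(range(2004, 2010),
                                     [10, 12, 14, 2, 2, 3])
        res = anova_pre_post(series, 2007)
        F, df1, df2 = anova_oracle([10, 12, 14], [2, 2, 3])
        assert res.F == pytest.approx(F, abs=1e-10)
        assert (res.df1, res.df2) == (df1, df2)

    def test_identical_groups_give_zero_F(self):
        series = _series_from_values(range(2004, 2010), [5, 5, 5, 5, 5, 5])
        res = anova_pre_post(series, 2007)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_twelve_year_split_has_df_1_10(self):
        rng = np.random.default_rng(1)
        series = _series_from_values(range(2004, 2016), rng.uniform(1, 9, 12))
        res = anova_pre_post(series, 2011)
        assert (res.df1, res.df2) == (1, 10)

    def test_random_inputs_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            vals = rng.uniform(0.5, 20, 9)
            series = _series_from_values(range(2000, 2009), vals)
            res = anova_pre_post(series, 2004)
            F, _, _ = anova_oracle(vals[:4], vals[4:])
            assert res.F == pytest.approx(F, abs=1e-10)

    def test_degenerate_group_rejected(self):
        series = _series_from_values(range(2004, 2008), [1, 2, 3, 4])
        with pytest.raises(DataError):
            anova_pre_post(series, 2007)


class TestFoldChange:
    def test_constant_series_is_one(self):
        series = _series_from_values(range(2004, 2012), [4.0] * 8)
        fc = fold_change(series, 2008)
        assert fc.ratio == pytest.approx(1.0)

    def test_zero_postdrought_mean_flagged_infinite(self):
        series = _series_from_values(range(2004, 2010), [5, 5, 5, 0, 0, 0])
        fc = fold_change(series, 2007)
        assert fc.infinite and np.isinf(fc.ratio)

    def test_split_year_belongs_to_post_by_default(self):
        series = _series_from_values(range(2004, 2008), [6, 6, 3, 3])
        fc = fold_change(series, 2006)
        assert fc.ratio == pytest.approx(2.0)


@pytest.fixture(scope="module")
def fitted_small(small_sim):
    spec = ModelSpec("poisson", "autoregressive",
                     gamma_covariates=("hot_days",))
    r = fit(small_sim.data, small_sim.covs, spec, starts=1, seed=0)
    return small_sim, r


class TestPosteriorAbundance:
    def test_perfect_detection_recovers_counts(self):
        """With p = 1 the posterior concentrates on the observed count."""
        rng = np.random.default_rng(12)
        M, T = 6, 4
        N = rng.integers(0, 9, (M, T))
        counts = N[:, :, None].astype(float)
        data = CountData([f"s{i}" for i in range(M)],
                         np.arange(2004, 2004 + T), counts,
                         np.zeros((M, T, 1)), np.zeros((M, T, 1)))
        spec = ModelSpec("poisson", "constant", K=20)
        from lekmix.types import FitResult, ParameterLayout
        layout = ParameterLayout.for_spec(spec)
        params = np.array([np.log(4.0), np.log(2.0), 0.3, 60.0])  # p -> 1
        fr = FitResult(spec=spec, layout=layout, params=params,
                       se=np.zeros(4), vcov=np.zeros((4, 4)), nll=0.0,
                       n_obs=data.n_observations, converged=True,
                       hessian_pd=True, K=20)
        series = posterior_abundance(fr, data, CovariateTable(),
                                     interval_draws=0)
        got = series.site_year.pivot(index="lek_id", columns="year",
                                     values="mean").to_numpy()
        order = np.argsort(data.site_ids)
        np.testing.assert_allclose(got, N[order], atol=1e-6)

    def test_posterior_beats_raw_max_counts(self, fitted_small):
        """Detection-corrected means track latent truth better than the
        naive per-season maximum count (detection < 1)."""
        sim, r = fitted_small
        series = posterior_abundance(r, sim.data, sim.covs,
                                     interval_draws=0)
        est = series.site_year.pivot(index="lek_id", columns="year",
                                     values="mean")
        est = est.loc[sim.data.site_ids].to_numpy()
        truth = sim.truth["N"].astype(float)
        with np.errstate(all="ignore"):
            rawmax = np.nanmax(sim.data.counts, axis=2)
        obs = ~np.isnan(rawmax)
        mae_post = np.abs(est - truth)[obs].mean()
        mae_raw = np.abs(rawmax - truth)[obs].mean()
        assert mae_post < mae_raw

    def test_unobserved_season_has_wider_interval(self, fitted_small):
        sim, r = fitted_small
        data = sim.data.mask_years([int(sim.data.years[3])])
        series = posterior_abundance(r, data, sim.covs, interval_draws=0)
        sy = series.site_year
        width = (sy["hi95"] - sy["lo95"]).groupby(sy["year"]).mean()
        masked = int(sim.data.years[3])
        neighbours = [int(sim.data.years[2]), int(sim.data.years[4])]
        assert all(width[masked] > width[y] for y in neighbours)

    def test_interval_draws_add_year_bounds(self, fitted_small):
        sim, r = fitted_small
        series = posterior_abundance(r, sim.data, sim.covs,
                                     interval_draws=40, seed=1)
        ys = series.year_summary
        assert {"lo95", "hi95"} <= set(ys.columns)
        assert (ys["lo95"] <= ys["mean"] + 1e-9).all()
        assert (ys["hi95"] >= ys["mean"] - 1e-9).all()

    def test_nonconverged_fit_rejected(self, fitted_small):
        sim, r = fitted_small
        import dataclasses
        bad = dataclasses.replace(r, converged=False)
        with pytest.raises(FitError):
            posterior_abundance(bad, sim.data, sim.covs)

    def test_interval_coverage_of_latent_truth(self, fitted_small):
        sim, r = fitted_small
        series = posterior_abundance(r, sim.data, sim.covs,
                                     interval_draws=0)
        sy = series.site_year.set_index(["lek_id", "year"])
        hits = total = 0
        for i, lek in enumerate(sim.data.site_ids):
            for t, year in enumerate(sim.data.years):
                lo = sy.loc[(lek, year), "lo95"]
                hi = sy.loc[(lek, year), "hi95"]
                hits += lo <= sim.truth["N"][i, t] <= hi
                total += 1
        assert hits / total >= 0.90
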