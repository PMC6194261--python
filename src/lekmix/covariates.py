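"""Weather and grazing covariate construction.

Year-level drought covariates follow the conventions of long-term lek
monitoring on the Southern High Plains: annual precipitation (cm), the
annual mean and minimum of the modified Palmer Drought Index (PMDI,
negative = drier), annual maximum temperature (deg C), and "hot days" --
the number of days whose daily maximum exceeds the long-run 90th
percentile of daily maxima (35 deg C for this system).  Seasonal
aggregates use winter = Dec(t-1)-Feb(t), breeding = Mar-May,
summer = Jun-Aug, fall = Sep-Nov.  Grazing pressure is summarised as cow
days/ha = cattle x days grazed / pasture area, summed over rotations
within a year.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import CountData, CovariateTable, DataError

__all__ = ["hot_days", "cow_days_per_ha", "seasonal_aggregate",
           "build_seasonal_table", "classify_wet_dry", "pearson_r",
           "ANNUAL_WEATHER", "SEASONS", "HOT_DAY_THRESHOLD_C",
           "PRECIP_P25_CM", "PRECIP_P75_CM", "build_covariate_table",
           "cow_days_site_year"]

#: annual weather covariate column names
ANNUAL_WEATHER = ("precip", "pmdi_avg", "pmdi_min", "tmax", "hot_days")

#: season -> calendar months; December belongs to the *following* year's
#: winter (winter of year t spans Dec t-1 .. Feb t)
SEASONS = {"winter": (12, 1, 2), "breeding": (3, 4, 5),
           "summer": (6, 7, 8), "fall": (9, 10, 11)}

HOT_DAY_THRESHOLD_C = 35.0      # long-run 90th percentile of daily maxima
PRECIP_P25_CM = 32.0            # 25th percentile of annual precip, 1950-2015
PRECIP_P75_CM = 46.0            # 75th percentile


def hot_days(daily_tmax, threshold: float = HOT_DAY_THRESHOLD_C) -> int:
    """Number of days with maximum temperature strictly above ``threshold``."""
    x = np.asarray(daily_tmax, dtype=float)
    if x.size == 0:
        raise DataError("empty daily temperature series")
    return int(np.sum(x > threshold))


def cow_days_per_ha(n_cattle, days, area_ha) -> float:
    """Grazing pressure: cattle x days grazed / pasture area (ha).

    Array inputs are treated as rotations within the year and summed.
    """
    n = np.asarray(n_cattle, dtype=float)
    d = np.asarray(days, dtype=float)
    a = np.asarray(area_ha, dtype=float)
    if np.any(a <= 0):
        raise DataError("pasture area must be positive")
    if np.any(n < 0) or np.any(d < 0):
        raise DataError("cattle and days must be nonnegative")
    return float(np.sum(n * d / a))


def seasonal_aggregate(monthly: pd.DataFrame, season: str, year: int,
                       value_col: str = "value", how: str = "sum") -> float:
    """Seasonal total (precipitation) or mean (PMDI) from a monthly table.

    ``monthly`` needs columns ``year``, ``month`` and ``value_col``.
    Winter of year t uses December of t-1 with January-February of t.
    An incomplete season yields NaN, never a partial aggregate.
    """
    if season not in SEASONS:
        raise DataError(f"unknown season {season!r}")
    vals = []
    for m in SEASONS[season]:
        y = year - 1 if (season == "winter" and m == 12) else year
        row = monthly[(monthly["year"] == y) & (monthly["month"] == m)]
        if len(row) != 1 or pd.isna(row[value_col].iloc[0]):
            return float("nan")
        vals.append(float(row[value_col].iloc[0]))
    return float(np.sum(vals)) if how == "sum" else float(np.mean(vals))


def build_seasonal_table(monthly: pd.DataFrame, value_col: str,
                         how: str, prefix: str) -> pd.DataFrame:
    """Year x season table of seasonal aggregates, columns ``prefix_season``."""
    years = sorted(monthly["year"].unique())
    out = {}
    for season in SEASONS:
        out[f"{prefix}_{season}"] = [
            seasonal_aggregate(monthly, season, y, value_col, how)
            for y in years]
    return pd.DataFrame(out, index=pd.Index(years, name="year"))


def classify_wet_dry(annual_precip: float, p25: float = PRECIP_P25_CM,
                     p75: float = PRECIP_P75_CM) -> str:
    """Classify a year as dry (< p25), wet (> p75) or normal (strict bounds)."""
    if not p25 < p75:
        raise DataError("p25 must be below p75")
    if annual_precip < p25:
        return "dry"
    if annual_precip > p75:
        return "wet"
    return "normal"


def pearson_r(x, y) -> float:
    """Product-moment correlation with pairwise-complete filtering."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise DataError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
def cow_days_site_year(grazing: pd.DataFrame, data: CountData) -> np.ndarray:
    """(M, T) cow days/ha per lek-year from pasture grazing records.

    Rotations within a (pasture, year) are summed; when a lek spans
    several pastures the pasture values are combined as an area-weighted
    mean.  Years with no record stay NaN.
    """
    need = {"pasture_id", "lek_id", "year", "n_cattle", "days_grazed",
            "area_ha"}
    missing = need - set(grazing.columns)
    if missing:
        raise DataError(f"grazing table missing columns: {sorted(missing)}")
    out = np.full((data.M, data.T), np.nan)
    sidx = {s: i for i, s in enumerate(data.site_ids)}
    yidx = {int(y): t for t, y in enumerate(data.years)}
    grouped = grazing.dropna(subset=["n_cattle", "days_grazed"]).groupby(
        ["lek_id", "year", "pasture_id"])
    acc: dict = {}
    for (lek, year, _past), g in grouped:
        if lek not in sidx or int(year) not in yidx:
            continue
        area = float(g["area_ha"].iloc[0])
        cd = cow_days_per_ha(g["n_cattle"], g["days_grazed"], area)
        acc.setdefault((sidx[lek], yidx[int(year)]), []).append((cd, area))
    for (i, t), vals in acc.items():
        cds, areas = np.array(vals).T
        out[i, t] = np.average(cds, weights=areas)
    return out


def build_covariate_table(year_table: pd.DataFrame,
                          grazing: pd.DataFrame | None = None,
                          data: CountData | None = None,
                          prior_counts: np.ndarray | None = None,
                          add_lags: bool = True) -> CovariateTable:
    """Assemble a :class:`CovariateTable` from the standard input tables."""
    tab = year_table.copy()
    if "year" in tab.columns:
        tab = tab.set_index("year")
    tab.index = tab.index.astype(int)
    covs = CovariateTable(year=tab)
    if add_lags:
        covs = covs.with_lags()
    if grazing is not None and data is not None:
        covs.site_year["cow_days"] = cow_days_site_year(grazing, data)
    if prior_counts is not None:
        covs.site["prior_count"] = np.asarray(prior_counts, dtype=float)
    return covs
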