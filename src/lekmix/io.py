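"""Plain-text input/output: the three CSV inputs, results, and run configs.

Formats (missing values are empty cells, never sentinel numbers):

* ``counts.csv``: lek_id, year, visit, date (ISO-8601), count,
  daily_rain_cm, daily_tmax_c — one row per completed visit.
* ``year_covariates.csv``: year plus annual and seasonal weather columns.
* ``grazing.csv``: pasture_id, lek_id, year, n_cattle, days_grazed,
  area_ha — one row per (pasture, lek, year) grazing record.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import build_covariate_table
from .types import CountData, CovariateTable, DataError, FitResult

__all__ = ["read_counts", "write_counts", "read_year_covariates",
           "write_year_covariates", "read_grazing", "write_grazing",
           "write_fit", "write_table", "write_series", "load_config",
           "assemble_covariates"]

_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{what} is missing columns {missing}")


def read_counts(path) -> tuple:
    """Read the long-format count table; returns (CountData, DataFrame).

    Schema violations are reported with 1-based data row numbers.
    """
    df = pd.read_csv(path)
    _require_columns(df, CountData.LONG_COLUMNS, "counts table")
    problems = []
    for k, row in enumerate(df.itertuples(index=False), start=1):
        if pd.isna(row.count) or row.count < 0 or row.count != int(row.count):
            problems.append(f"row {k}: count {row.count!r} is not a "
                            "nonnegative integer")
        if not pd.isna(row.date) and str(row.date) \
                and not _DATE_RE.match(str(row.date)):
            problems.append(f"row {k}: date {row.date!r} is not ISO-8601")
        if pd.isna(row.year) or row.year != int(row.year):
            problems.append(f"row {k}: year {row.year!r} is not an integer")
    if problems:
        raise DataError("invalid counts table:\n" + "\n".join(problems[:20]))
    years = sorted(df["year"].unique())
    if list(range(int(years[0]), int(years[-1]) + 1)) != [int(y)
                                                          for y in years]:
        raise DataError(f"survey years are not contiguous: {years}")
    return CountData.from_long(df), df


def write_counts(data: CountData, path, dates=None) -> None:
    data.to_long(dates).to_csv(path, index=False, na_rep="")


def read_year_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["year"], "year covariate table")
    return df


def write_year_covariates(table: pd.DataFrame, path) -> None:
    out = table.reset_index() if table.index.name == "year" else table
    out.to_csv(path, index=False, na_rep="")


def read_grazing(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["pasture_id", "lek_id", "year", "n_cattle",
                          "days_grazed", "area_ha"], "grazing table")
    return df


def write_grazing(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")


def assemble_covariates(year_table: pd.DataFrame,
                        grazing: pd.DataFrame | None,
                        data: CountData,
                        prior_counts=None) -> CovariateTable:
    """Join the year table and grazing records into a CovariateTable.

    Lag columns are added unless already present in the year table.
    """
    has_lags = any(c.endswith("_lag1") for c in year_table.columns)
    return build_covariate_table(year_table, grazing=grazing, data=data,
                                 prior_counts=prior_counts,
                                 add_lags=not has_lags)


# ---------------------------------------------------------------------------
def write_fit(fitres: FitResult, outdir) -> None:
    """FitResult as fit.json plus a flat coefficients.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "fit.json", "w") as fh:
        json.dump(fitres.to_dict(), fh, indent=1)
    fitres.coef_table().to_csv(outdir / "coefficients.csv", index=False,
                               na_rep="")


#: Table-2-style column layout for candidate tables
_CANDIDATE_COLUMNS = ["process", "covariate", "period", "dAIC", "weight",
                      "weight_process", "beta", "lcl", "ucl", "converged"]


def write_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in _CANDIDATE_COLUMNS if c in table.columns]
    out = table[cols] if cols else table
    out.to_csv(path, index=False, na_rep="")


def write_series(series, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series.site_year.to_csv(outdir / "abundance_site_year.csv", index=False,
                            na_rep="")
    series.year_summary.to_csv(outdir / "abundance_year_summary.csv",
                               index=False, na_rep="")


# ---------------------------------------------------------------------------
_CONFIG_KEYS = {"seed", "output", "scenario", "inputs", "model",
                "selection", "estimate", "verbose"}


def load_config(path) -> dict:
    """Load a YAML run config; unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DataError("config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise DataError(f"unknown config keys: {sorted(unknown)}")
    return cfg
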