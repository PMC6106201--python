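"""Defoliation covariates for the count model.

Two predictors enter the model. The local predictor ``b1`` is the
proportion of the area around a survey route affected by moderate-to-
severe defoliation in the current year. The regional predictor ``b2`` is
the trailing mean, over the preceding ``lag_window`` years (default 4),
of the stratum-wide annual defoliated proportion ``b2_raw``; the lag
reflects the delay between a sustained outbreak and the dispersal of the
birds it recruited. An era indicator ``I1`` is 1 only in years for which
the trailing mean can be computed (and which fall after the configured
cutoff), so counts from the earliest survey years remain in the
likelihood with the regional term switched off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariateTable",
    "era_indicator",
    "regional_lagged_mean",
    "build_covariate_table",
]

LOCAL_COLUMNS = ["stratum", "route", "year", "b1"]
REGIONAL_COLUMNS = ["stratum", "year", "b2_raw"]
STRATUM_YEAR_COLUMNS = ["stratum", "year", "b2_raw", "b2", "I1"]


def era_indicator(year, cutoff: int = 1969):
    """Indicator for the era in which the regional predictor is defined.

    Returns 1 for years strictly greater than ``cutoff``, else 0. With the
    historical survey start of 1966 and a 4-year lag the cutoff is 1969:
    1970 is the first year with a full trailing window.
    """
    out = (np.asarray(year) > cutoff).astype(int)
    if np.isscalar(year):
        return int(out)
    return out


def regional_lagged_mean(b2_raw_series: pd.Series, lag_window: int = 4) -> pd.Series:
    """Trailing mean of the previous ``lag_window`` years, excluding the current year.

    ``b2_raw_series`` must be indexed by consecutive integer years. The
    value at year ``t`` is ``mean(x[t-1], ..., x[t-lag_window])``; the first
    ``lag_window`` years of the series are NaN (no full window).
    """
    if lag_window < 1:
        raise ValueError("lag_window must be >= 1")
    series = pd.Series(b2_raw_series).astype(float)
    years = np.asarray(series.index)
    if len(series) > 1 and not np.array_equal(years, np.arange(years[0], years[0] + len(years))):
        raise ValueError("series must be indexed by consecutive years")
    return series.rolling(lag_window).mean().shift(1)


def _check_proportions(values, name: str) -> None:
    arr = np.asarray(values, dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class CovariateTable:
    """Aligned local and regional defoliation predictors.

    ``route_year`` has columns (stratum, route, year, b1); ``stratum_year``
    has (stratum, year, b2_raw, b2, I1). Rows with I1 = 0 carry b2 = 0 by
    convention — the regional term is gated by I1 in the model, so the
    stored value is never used there.
    """

    route_year: pd.DataFrame
    stratum_year: pd.DataFrame
    lag_window: int = 4
    cutoff: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.route_year = self.route_year.reset_index(drop=True)
        self.stratum_year = self.stratum_year.reset_index(drop=True)
        for col in LOCAL_COLUMNS:
            if col not in self.route_year.columns:
                raise ValueError(f"route_year missing column {col!r}")
        for col in STRATUM_YEAR_COLUMNS:
            if col not in self.stratum_year.columns:
                raise ValueError(f"stratum_year missing column {col!r}")
        _check_proportions(self.route_year["b1"], "b1")
        _check_proportions(self.stratum_year["b2_raw"], "b2_raw")
        _check_proportions(self.stratum_year["b2"], "b2")
        i1 = self.stratum_year["I1"].to_numpy()
        if i1.size and not np.isin(i1, (0, 1)).all():
            raise ValueError("I1 must be 0/1")

    def merged(self) -> pd.DataFrame:
        """Route-year table joined with its stratum-year regional values."""
        out = self.route_year.merge(
            self.stratum_year, on=["stratum", "year"], how="left", validate="m:1"
        )
        if out[["b2", "I1"]].isna().any().any():
            raise ValueError("route-year rows without a matching stratum-year row")
        return out

    def is_empty(self) -> bool:
        return self.route_year.empty


def build_covariate_table(
    local_table: pd.DataFrame,
    regional_raw_table: pd.DataFrame,
    cutoff: int | None = None,
    lag_window: int = 4,
) -> CovariateTable:
    """Assemble a :class:`CovariateTable` from raw defoliation tables.

    ``local_table`` holds per-route-per-year local proportions (columns
    stratum, route, year, b1); ``regional_raw_table`` holds per-stratum
    annual regional proportions (stratum, year, b2_raw). ``cutoff``
    defaults to ``first regional year + lag_window - 1``, i.e. the era
    indicator switches on in the first year with a complete trailing
    window. Years whose window is incomplete always get I1 = 0 and b2 = 0.
    """
    local = pd.DataFrame(local_table)
    regional = pd.DataFrame(regional_raw_table)
    if local.empty:
        warnings.warn("empty local covariate table; emitting empty CovariateTable")
        empty_sy = pd.DataFrame(columns=STRATUM_YEAR_COLUMNS)
        empty_ry = pd.DataFrame(columns=LOCAL_COLUMNS)
        return CovariateTable(empty_ry, empty_sy, lag_window=lag_window, cutoff=cutoff)

    for col in LOCAL_COLUMNS:
        if col not in local.columns:
            raise ValueError(f"local table missing column {col!r}")
    for col in REGIONAL_COLUMNS:
        if col not in regional.columns:
            raise ValueError(f"regional table missing column {col!r}")
    _check_proportions(local["b1"], "b1")
    _check_proportions(regional["b2_raw"], "b2_raw")

    local_strata = set(local["stratum"].unique())
    regional_strata = set(regional["stratum"].unique())
    if local_strata != regional_strata:
        raise ValueError(
            "stratum sets differ between local and regional tables: "
            f"{sorted(local_strata ^ regional_strata)}"
        )
    local_years = set(local["year"].unique())
    regional_years = set(regional["year"].unique())
    if not local_years <= regional_years:
        raise ValueError("local table contains years absent from the regional table")

    if cutoff is None:
        cutoff = int(regional["year"].min()) + lag_window - 1

    pieces = []
    for stratum, grp in regional.sort_values("year").groupby("stratum", sort=True):
        series = grp.set_index("year")["b2_raw"]
        lagged = regional_lagged_mean(series, lag_window=lag_window)
        i1 = era_indicator(series.index.to_numpy(), cutoff=cutoff) & (~lagged.isna()).to_numpy()
        piece = pd.DataFrame(
            {
                "stratum": stratum,
                "year": series.index,
                "b2_raw": series.to_numpy(),
                "b2": np.where(i1 == 1, lagged.fillna(0.0).to_numpy(), 0.0),
                "I1": i1.astype(int),
            }
        )
        pieces.append(piece)
    stratum_year = pd.concat(pieces, ignore_index=True)

    return CovariateTable(
        local[LOCAL_COLUMNS].copy(), stratum_year, lag_window=lag_window, cutoff=cutoff
    )
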