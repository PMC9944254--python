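"""CO2 growth rate (CGR) from monthly station concentrations.

The growth rate is the first-order difference of CO2 between two successive
months. Summed over a calendar year it telescopes to the December-to-December
concentration change; summed over a sliding 12-month block it gives the
high-frequency growth rate. Both are converted from ppm to PgC with the
standard airborne-mass factor (2.124 PgC per ppm).

The backward difference for month m is assigned to m, so the annual sum for
year y uses the January–December differences of y and equals
co2(Dec y) − co2(Dec y−1). A record spanning Dec 1959–Dec 2020 therefore
yields 732 monthly growth-rate values (Jan 1960–Dec 2020), 721 twelve-month
windows and 61 annual values, 59 of which survive the 1992–1993 (Mt Pinatubo)
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import StationRecord
from .utils import window_center_position

PPM_TO_PGC = 2.124


class EmptySeriesError(ValueError):
    """No usable data points."""


@dataclass
class CGRSeries:
    """Annual or high-frequency CO2 growth rate in PgC per year.

    ``values`` is indexed by calendar year (annual) or by the center month of
    the 12-month block (highfreq, monthly PeriodIndex). ``excluded`` flags
    entries omitted from downstream fits but retained for bookkeeping.
    """

    kind: str  # "annual" | "highfreq"
    values: pd.Series
    excluded: pd.Series
    station_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("annual", "highfreq"):
            raise ValueError(f"unknown CGR kind {self.kind!r}")
        if not self.values.index.equals(self.excluded.index):
            raise ValueError("values and excluded must share an index")

    @property
    def usable(self) -> pd.Series:
        """Non-excluded, non-missing entries."""
        keep = ~self.excluded & self.values.notna()
        return self.values[keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value_pgc": self.values, "excluded": self.excluded})


def monthly_cgr(record: StationRecord) -> pd.Series:
    """Monthly CO2 growth rate in ppm per month (backward first difference).

    The difference for month m is co2(m) − co2(m−1); the result has one fewer
    entry than the record and differences across a missing month are missing.
    """
    co2 = record.data.astype(float)
    if co2.notna().sum() < 2 or not (co2.notna() & co2.shift(1).notna()).any():
        raise EmptySeriesError("need at least two consecutive non-missing months")
    diffs = co2.diff().iloc[1:]
    diffs.name = "cgr_ppm_per_month"
    return diffs


def annual_cgr(monthly: pd.Series, excluded_years=(1992, 1993),
               factor: float = PPM_TO_PGC, station_id: str = "") -> CGRSeries:
    """Annual CGR: calendar-year sum of monthly differences, converted to PgC/y.

    Years without all 12 monthly differences are marked missing. Excluded
    years are flagged but retained.
    """
    if not isinstance(monthly.index, pd.PeriodIndex):
        raise TypeError("monthly series must use a monthly PeriodIndex")
    years = monthly.index.year
    grouped = monthly.groupby(years)
    sums = grouped.sum(min_count=12)
    counts = grouped.size()
    complete = (counts == 12) & grouped.count().eq(12)
    values = (sums * factor).where(complete)
    values.index.name = "year"
    values.name = "cgr_pgc_per_year"
    excluded = pd.Series(np.isin(values.index, list(excluded_years)), index=values.index,
                         name="excluded")
    return CGRSeries(kind="annual", values=values, excluded=excluded, station_id=station_id)


def highfreq_cgr(monthly: pd.Series, window_months: int = 12,
                 factor: float = PPM_TO_PGC, excluded_years=(),
                 station_id: str = "") -> CGRSeries:
    """High-frequency CGR: sliding ``window_months``-sum of monthly differences.

    Entries are labeled by the block-center month (the 6th month of a
    12-month block) and scaled to PgC per year via ``factor`` (a 12-month sum
    of ppm/month differences is a ppm/year rate). Length is
    ``len(monthly) − window_months + 1``.
    """
    if not isinstance(monthly.index, pd.PeriodIndex):
        raise TypeError("monthly series must use a monthly PeriodIndex")
    n = len(monthly)
    if n < window_months:
        raise EmptySeriesError(
            f"series of {n} months is shorter than the {window_months}-month window")
    sums = monthly.rolling(window_months, min_periods=window_months).sum()
    values = (sums.iloc[window_months - 1:] * factor * (12.0 / window_months))
    offset = window_center_position(0, window_months)
    centers = monthly.index[offset:offset + len(values)]
    values = pd.Series(values.to_numpy(), index=centers, name="cgr_pgc_per_year")
    if excluded_years:
        # a block is flagged if any of its months falls in an excluded year
        flag = np.zeros(n, dtype=bool)
        flag[np.isin(monthly.index.year, list(excluded_years))] = True
        block_any = pd.Series(flag).rolling(window_months).max().iloc[window_months - 1:]
        excluded = pd.Series(block_any.to_numpy(dtype=bool), index=centers, name="excluded")
    else:
        excluded = pd.Series(False, index=centers, name="excluded")
    return CGRSeries(kind="highfreq", values=values, excluded=excluded, station_id=station_id)
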