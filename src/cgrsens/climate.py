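"""Tropical-mean climate series, detrended anomalies and bi-decadal means.

Temperature sensitivity of the growth rate is estimated from interannual
anomalies: each tropical-mean series is reduced to its residual around the
full-period ordinary-least-squares line ("detrended anomaly"). Water
availability at the decadal scale is summarized by a 20-year moving mean of
annual precipitation ("bi-decadal precipitation").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .cgr import CGRSeries
from .utils import window_center_year


def tropical_mean(field: xr.DataArray, band: tuple[float, float] = (24.0, -24.0),
                  mask: xr.DataArray | None = None, area_weighted: bool = True) -> pd.Series:
    """Spatial mean over (masked) vegetated land within a latitude band.

    Cells are weighted by cos(latitude) (set ``area_weighted=False`` for a
    plain cell mean); missing cells are ignored with weight renormalization.
    """
    north, south = max(band), min(band)
    sub = field.where((field["lat"] <= north) & (field["lat"] >= south))
    if mask is not None:
        sub = sub.where(mask.astype(bool))
    if area_weighted:
        w = np.cos(np.deg2rad(sub["lat"]))
    else:
        w = xr.ones_like(sub["lat"], dtype=float)
    w2d = w.broadcast_like(sub.isel(time=0, drop=True))
    valid = sub.notnull()
    if not bool(valid.any()):
        raise ValueError("no unmasked cells inside the latitude band")
    num = (sub * w2d).sum(dim=("lat", "lon"), skipna=True)
    den = w2d.where(valid).sum(dim=("lat", "lon"), skipna=True)
    out = (num / den).to_series()
    if "year" in field.coords and "month" in field.coords:
        idx = pd.PeriodIndex.from_fields(year=field["year"].values, month=field["month"].values, freq="M")
        out.index = idx
    out.name = field.name
    return out


def detrend_linear(series: pd.Series) -> pd.Series:
    """Residual around the full-period OLS line; NaNs are preserved in place.

    Idempotent: detrending an anomaly series returns it unchanged (to
    floating-point precision).
    """
    y = np.asarray(series, dtype=float)
    idx = series.index if isinstance(series, pd.Series) else None
    if isinstance(idx, pd.PeriodIndex):
        t = idx.asi8.astype(float)
    elif idx is not None and pd.api.types.is_numeric_dtype(idx):
        t = np.asarray(idx, dtype=float)
    else:
        t = np.arange(len(y), dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing points to detrend")
    slope, intercept = np.polyfit(t[ok], y[ok], 1)
    resid = y - (slope * t + intercept)
    if isinstance(series, pd.Series):
        return pd.Series(resid, index=series.index, name=series.name)
    return pd.Series(resid)


def bidecadal_mean(series: pd.Series, window_years: int = 20) -> pd.Series:
    """Sliding ``window_years``-mean of an annual series, center-labeled.

    Output length is ``n − window_years + 1``; the label of the window starting
    at year y is ``y + window_years//2``, matching the moving-window
    sensitivity labels.
    """
    n = len(series)
    if n < window_years:
        raise ValueError(f"series of {n} points shorter than {window_years}-year window")
    vals = series.rolling(window_years).mean().iloc[window_years - 1:]
    starts = np.asarray(series.index[: n - window_years + 1], dtype=int)
    centers = np.array([window_center_year(s, window_years) for s in starts])
    return pd.Series(vals.to_numpy(), index=pd.Index(centers, name="center"),
                     name=series.name)


def annual_anomalies(monthly: pd.DataFrame, precip_col: str = "P") -> pd.DataFrame:
    """Aggregate monthly tropical means to annual values and detrend.

    Temperature and radiation are annual means; the ``precip_col`` column is
    an annual total (mm/month values sum to mm/y). Returns columns T, P, R
    and their detrended anomalies dT, dP, dR; incomplete years are dropped.
    """
    if not isinstance(monthly.index, pd.PeriodIndex):
        raise TypeError("monthly table must use a monthly PeriodIndex")
    years = monthly.index.year
    counts = monthly.groupby(years).size()
    agg = {}
    for col in monthly.columns:
        grouped = monthly[col].groupby(years)
        if col == precip_col:
            agg[col] = grouped.sum(min_count=12)
        else:
            agg[col] = grouped.mean()
    out = pd.DataFrame(agg)
    out = out[counts == 12]  # complete years only
    out.index.name = "year"
    for col in list(out.columns):
        out["d" + col] = detrend_linear(out[col])
    return out


def align(cgr: CGRSeries, anomalies: pd.DataFrame) -> pd.DataFrame:
    """Inner-join a CGR series with an anomaly table on their common index.

    The joined table carries the growth rate as ``cgr`` plus its exclusion
    flag; excluded rows are kept (flagged) so window bookkeeping stays
    transparent.
    """
    table = anomalies.join(
        pd.DataFrame({"cgr": cgr.values, "excluded": cgr.excluded}), how="inner")
    table = table.dropna(subset=["cgr"])
    if table.empty:
        raise ValueError("CGR series and anomaly table have no overlapping index")
    return table
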