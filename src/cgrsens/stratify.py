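"""Dryness stratification of the temperature sensitivity.

Water availability (detrended precipitation, scPDSI, SPEI, soil moisture or
water storage) is standardized by the full-record standard deviation and
split into four categories: very wet (sigma >= 1), wet (0 <= sigma < 1),
dry (-1 <= sigma < 0) and very dry (sigma < -1). Within each category the
pooled high-frequency rows are refitted to give a per-category gamma with
bootstrap uncertainty. The same sigma rule applied across space (to pixel
long-term means) yields spatial dryness groups.

Note the category rule as printed leaves sigma = -1 in "dry" (the 'very dry'
bound is strict) while sigma = +1 belongs to "very wet"; the boundaries are
implemented exactly as stated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .climate import detrend_linear, tropical_mean
from .sensitivity import fit_window, bootstrap_sd, _COEF_NAMES

CATEGORIES = ("very_dry", "dry", "wet", "very_wet")


def standardize(anomalies: pd.Series, ddof: int = 0) -> pd.Series:
    """Sigma-scores: detrended anomalies divided by their full-period SD.

    Uses the population SD (ddof=0) by default; the mean is not re-subtracted
    (anomalies are already centered by detrending), so standardizing twice is
    a fixed point.
    """
    vals = np.asarray(anomalies, dtype=float)
    ok = np.isfinite(vals)
    if ok.sum() < 3:
        raise ValueError("need at least 3 points to standardize")
    sd = np.std(vals[ok], ddof=ddof)
    if sd == 0:
        raise ValueError("zero-variance series cannot be standardized")
    if abs(sd - 1.0) < 1e-12:
        sd = 1.0  # already on the sigma scale
    out = anomalies / sd
    if isinstance(out, pd.Series):
        out.name = "sigma"
    return out


def classify(scores) -> pd.Series:
    """Dryness category labels for sigma-scores (boundaries exactly as stated:
    sigma=1 -> very_wet, sigma=0 -> wet, sigma=-1 -> dry)."""
    s = np.asarray(scores, dtype=float)
    labels = np.select(
        [s >= 1.0, (s >= 0.0) & (s < 1.0), (s >= -1.0) & (s < 0.0), s < -1.0],
        ["very_wet", "wet", "dry", "very_dry"], default=None)
    idx = scores.index if isinstance(scores, pd.Series) else None
    return pd.Series(pd.Categorical(labels, categories=CATEGORIES), index=idx,
                     name="category")


def gamma_by_category(table: pd.DataFrame, labels: pd.Series, model: str = "M1",
                      reps: int = 500, seed=None) -> pd.DataFrame:
    """Pooled sensitivity fit per dryness category with bootstrap SD.

    ``table`` is a joined high-frequency table (cgr, dT, dP, dR, excluded);
    ``labels`` assigns each row a category. Categories with too few rows are
    reported with NaN gamma rather than raised.
    """
    labels = labels.reindex(table.index)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    min_n = len(_COEF_NAMES[model]) + 2
    rows = []
    for cat in CATEGORIES:
        block = table[(labels == cat).to_numpy()]
        n = len(block)
        if n < min_n:
            rows.append({"category": cat, "n": n, "gamma": np.nan, "gamma_sd": np.nan,
                         "model": model})
            continue
        est = fit_window(block, model=model)
        bs = bootstrap_sd(block, model=model, reps=reps, seed=rng)
        rows.append({"category": cat, "n": est.n_used, "gamma": est.gamma,
                     "gamma_sd": bs["gamma"], "model": model})
    return pd.DataFrame(rows).set_index("category")


def spatial_groups(mean_field: xr.DataArray, mask: xr.DataArray | None = None,
                   ddof: int = 0) -> xr.DataArray:
    """Dryness group of each pixel from the spatial distribution of its
    long-term mean.

    Each pixel's long-term mean is standardized against the mean and SD of the
    masked pixel population, then classified with the temporal sigma rule.
    Returns an integer layer (0 very_dry .. 3 very_wet, -1 outside the mask).
    """
    field = mean_field
    if mask is not None:
        if mask.shape != mean_field.shape:
            raise ValueError("mask grid does not match the field grid")
        field = mean_field.where(mask.astype(bool))
    vals = field.values
    ok = np.isfinite(vals)
    if ok.sum() < 2:
        raise ValueError("need at least 2 unmasked pixels")
    mu, sd = vals[ok].mean(), vals[ok].std(ddof=ddof)
    sigma = (vals - mu) / sd if sd > 0 else np.zeros_like(vals)
    codes = np.full(vals.shape, -1, dtype=np.int8)
    codes[ok & (sigma < -1.0)] = 0
    codes[ok & (sigma >= -1.0) & (sigma < 0.0)] = 1
    codes[ok & (sigma >= 0.0) & (sigma < 1.0)] = 2
    codes[ok & (sigma >= 1.0)] = 3
    return xr.DataArray(codes, coords=mean_field.coords, dims=mean_field.dims,
                        name="dryness_group",
                        attrs={"labels": "0=very_dry 1=dry 2=wet 3=very_wet -1=masked"})


def group_mean_series(field: xr.DataArray, groups: xr.DataArray,
                      area_weighted: bool = True) -> pd.DataFrame:
    """Cos-latitude-weighted mean time series of a field per dryness group."""
    out = {}
    for code, name in enumerate(CATEGORIES):
        sel = groups == code
        if not bool(sel.any()):
            continue
        out[name] = tropical_mean(field, band=(90.0, -90.0), mask=sel,
                                  area_weighted=area_weighted)
    return pd.DataFrame(out)
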