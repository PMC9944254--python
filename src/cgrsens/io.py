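"""Readers and writers for the formats the pipeline touches.

Station CO2 records are columnar text (year month ppm [flag]), whitespace- or
comma-separated, with ``#`` comment lines — the dialect family used by the
NOAA GML monthly flask/in-situ products. Gridded climate enters as
CF-convention NetCDF with (time, lat, lon) dimensions. All tabular outputs are
plain CSV next to a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .config import RunConfig
from .utils import monthly_period_index

logger = logging.getLogger("cgrsens")


class StationFormatError(ValueError):
    """A station CO2 file could not be parsed."""


class GriddedFormatError(ValueError):
    """A gridded NetCDF file does not satisfy the expected layout."""


@dataclass
class StationRecord:
    """Monthly station CO2 concentrations.

    ``data`` is a float Series on a monthly PeriodIndex, gap-filled with NaN so
    the calendar is contiguous; missing months are explicit NaN.
    """

    station_id: str
    data: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.PeriodIndex):
            raise TypeError("StationRecord.data must use a monthly PeriodIndex")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("CO2 concentrations must be positive or missing")

    @property
    def n_months(self) -> int:
        return len(self.data)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum())


def read_station_co2(path, dialect: str = "auto", station_id: str | None = None,
                     missing_below: float = 0.0) -> StationRecord:
    """Parse a columnar station CO2 file into a :class:`StationRecord`.

    Parameters
    ----------
    path:
        Text file with at least three columns: year, month, CO2 (ppm). Extra
        columns are kept as flags but ignored. Lines starting with ``#`` are
        comments.
    dialect:
        ``"auto"`` (default) accepts comma- or whitespace-separated rows;
        ``"csv"`` / ``"whitespace"`` force one separator.
    missing_below:
        Values at or below this threshold (e.g. the common ``-99.99`` fill)
        are treated as missing.
    """
    path = Path(path)
    rows: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "csv" or (dialect == "auto" and "," in line):
                parts = [p.strip() for p in line.split(",")]
            else:
                parts = line.split()
            if len(parts) < 3:
                raise StationFormatError(
                    f"{path.name}:{lineno}: expected at least 3 columns, got {len(parts)}")
            try:
                year, month, value = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise StationFormatError(f"{path.name}:{lineno}: unparseable row ({exc})") from exc
            if not 1 <= month <= 12:
                raise StationFormatError(f"{path.name}:{lineno}: month {month} out of range")
            rows.append((year, month, value))
    if not rows:
        raise StationFormatError(f"{path.name}: no data rows found")

    df = pd.DataFrame(rows, columns=["year", "month", "co2"])
    dupes = df.duplicated(subset=["year", "month"])
    if dupes.any():
        year, month = (int(v) for v in df.loc[dupes.idxmax(), ["year", "month"]])
        raise StationFormatError(f"{path.name}: duplicate entry for {year}-{month:02d}")
    order = df[["year", "month"]].apply(tuple, axis=1)
    if not order.is_monotonic_increasing:
        warnings.warn(f"{path.name}: rows not in calendar order; re-sorting", stacklevel=2)
        df = df.sort_values(["year", "month"], kind="mergesort").reset_index(drop=True)

    df.loc[df["co2"] <= missing_below, "co2"] = np.nan
    idx = pd.PeriodIndex.from_fields(year=df["year"], month=df["month"], freq="M")
    series = pd.Series(df["co2"].to_numpy(), index=idx, name="co2")
    # contiguous calendar with explicit gaps
    full = pd.period_range(idx[0], idx[-1], freq="M")
    series = series.reindex(full)
    return StationRecord(station_id=station_id or path.stem, data=series)


def write_station_co2(record: StationRecord, path) -> None:
    """Write a station record back to whitespace-separated text (NaN -> -99.99)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# station: {record.station_id}\n# year month co2_ppm\n")
        for per, val in record.data.items():
            out = -99.99 if not np.isfinite(val) else val
            fh.write(f"{per.year} {per.month} {out:.6f}\n")


def _normalize_longitudes(ds: xr.Dataset) -> xr.Dataset:
    if "lon" in ds.coords and float(ds["lon"].max()) > 180.0:
        lon = ((ds["lon"] + 180.0) % 360.0) - 180.0
        ds = ds.assign_coords(lon=lon).sortby("lon")
    return ds


def read_gridded(path, variables: list[str] | None = None) -> xr.Dataset:
    """Open a CF NetCDF file of monthly fields and validate its layout.

    Requires ``lat``, ``lon`` and a decodable monthly ``time`` coordinate.
    Longitudes on a 0–360 grid are remapped to −180–180. Integer ``year`` and
    ``month`` coordinates are attached along ``time``.
    """
    ds = xr.open_dataset(path)
    for coord in ("lat", "lon", "time"):
        if coord not in ds.coords and coord not in ds.dims:
            raise GriddedFormatError(f"missing coordinate '{coord}'")
    if variables:
        missing = [v for v in variables if v not in ds.data_vars]
        if missing:
            raise GriddedFormatError(
                f"variable(s) {missing} not in file; available: {sorted(ds.data_vars)}")
        keep = list(variables) + [v for v in ds.data_vars if v == "mask"]
        ds = ds[sorted(set(keep), key=keep.index)]
    times = pd.to_datetime(ds["time"].values)
    years = times.year.to_numpy()
    months = times.month.to_numpy()
    seqno = years * 12 + months
    if len(seqno) > 1 and not np.all(np.diff(seqno) == 1):
        raise GriddedFormatError("time coordinate is not a contiguous monthly sequence")
    ds = ds.assign_coords(year=("time", years), month=("time", months))
    return _normalize_longitudes(ds)


def write_gridded(ds: xr.Dataset, path) -> None:
    """Write a dataset as NetCDF3 classic (portable, text-tool friendly)."""
    enc = {v: {"dtype": "float64"} for v in ds.data_vars
           if np.issubdtype(ds[v].dtype, np.floating)}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def write_manifest(path, config: RunConfig, seed: int, outputs: dict | None = None,
                   extra: dict | None = None) -> None:
    """Record everything needed to reproduce a run: config, seed, versions."""
    import cgrsens

    manifest = {
        "package": "cgrsens",
        "version": cgrsens.__version__,
        "seed": int(seed),
        "config": config.to_dict(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "outputs": outputs or {},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
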