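"""Small shared helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd


def percent_change(old: float, new: float) -> float:
    """Relative change from ``old`` to ``new`` in percent: 100*(new-old)/old."""
    old = float(old)
    if old == 0:
        raise ZeroDivisionError("percent change from a zero baseline is undefined")
    return 100.0 * (float(new) - old) / old


def window_center_year(start: int, window_years: int) -> int:
    """Central calendar year used to label a window of ``window_years`` years."""
    return int(start) + window_years // 2


def window_center_position(start: int, window: int) -> int:
    """Index of the center element of a ``window``-long block starting at ``start``.

    For a 12-month block this is the 6th month (offset 5), the convention used
    to label high-frequency growth-rate windows.
    """
    return int(start) + window // 2 - 1


def monthly_period_index(start_year: int, start_month: int, n: int) -> pd.PeriodIndex:
    return pd.period_range(start=f"{start_year}-{start_month:02d}", periods=n, freq="M")


def as_float_array(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr
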