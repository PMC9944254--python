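"""Temperature sensitivity of the CO2 growth rate (gamma) by moving-window OLS.

The sensitivity gamma is the temperature coefficient of a multiple linear
regression of growth-rate anomalies on detrended climate anomalies,

    CGR = gamma*dT + tau*dP + delta*dR (+ theta*dT*dP) + eps,

fitted with an intercept inside each 20-year moving window. Model "M1" is the
plain multiple regression; "M2" adds the temperature-precipitation interaction
term. Uncertainty per window comes from a 500-member case-resampling
bootstrap.

The estimators follow the scikit-learn protocol (``fit``, ``predict``,
``get_params``) and the module-level functions ``fit_window``,
``moving_window``, ``bootstrap_sd`` and ``highfreq_sensitivity`` are thin
wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .utils import window_center_year, window_center_position

_COEF_NAMES = {"M1": ("gamma", "tau", "delta"), "M2": ("gamma", "tau", "delta", "theta")}
_REGRESSORS = ("dT", "dP", "dR")


class RankDeficientError(ValueError):
    """The regressor matrix is not full rank."""


def _design(X: np.ndarray, model: str, intercept: bool) -> np.ndarray:
    cols = [X[:, 0], X[:, 1], X[:, 2]]
    if model == "M2":
        cols.append(X[:, 0] * X[:, 1])
    if intercept:
        cols.append(np.ones(len(X)))
    return np.column_stack(cols)


def _check_rank(D: np.ndarray, model: str, intercept: bool) -> None:
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        names = list(_COEF_NAMES[model]) + (["intercept"] if intercept else [])
        sd = D.std(axis=0)
        degenerate = [n for n, s in zip(names, sd) if s == 0 and n != "intercept"]
        hint = f" (zero-variance: {degenerate})" if degenerate else ""
        raise RankDeficientError(
            f"design matrix rank {rank} < {D.shape[1]}; collinear regressors "
            f"among {names}{hint}")


class ClimateSensitivityRegression(RegressorMixin, BaseEstimator):
    """OLS sensitivity regression of growth-rate anomalies on climate anomalies.

    Parameters
    ----------
    model : {"M1", "M2"}
        "M1" regresses on (dT, dP, dR); "M2" adds the dT*dP interaction.
    fit_intercept : bool
        Include an intercept (anomalies are centered over the full period, not
        per window, so window means are generally nonzero).

    Attributes
    ----------
    gamma_, tau_, delta_, theta_ : float
        Sensitivities to temperature (PgC/y/K), precipitation (PgC/y per
        mm/y), radiation (PgC/y per native unit) and the T*P interaction
        (``theta_`` is NaN under M1).
    coef_ : ndarray
        Regression coefficients in model order (without intercept).
    se_ : ndarray
        Classical OLS standard errors for ``coef_``.
    r2_ : float
        Coefficient of determination of the fit.
    resid_ : ndarray
        Fit residuals.
    """

    def __init__(self, model: str = "M1", fit_intercept: bool = True):
        self.model = model
        self.fit_intercept = fit_intercept

    def _validate(self, X, y=None):
        if self.model not in _COEF_NAMES:
            raise ValueError(f"model must be 'M1' or 'M2', got {self.model!r}")
        if isinstance(X, pd.DataFrame):
            X = X[list(_REGRESSORS)].to_numpy(dtype=float) if set(_REGRESSORS) <= set(
                X.columns) else X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must have 3 columns: dT, dP, dR")
        if y is None:
            return X
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
        return X[ok], y[ok]

    def fit(self, X, y):
        X, y = self._validate(X, y)
        p = len(_COEF_NAMES[self.model])
        min_n = p + (2 if self.fit_intercept else 1)
        if len(y) < min_n:
            raise ValueError(f"need at least {min_n} rows to fit {self.model}, got {len(y)}")
        D = _design(X, self.model, self.fit_intercept)
        _check_rank(D, self.model, self.fit_intercept)
        beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
        fitted = D @ beta
        resid = y - fitted
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        dof = len(y) - D.shape[1]
        if dof > 0 and ss_res > 0:
            sigma2 = ss_res / dof
            cov = sigma2 * np.linalg.inv(D.T @ D)
            se = np.sqrt(np.diag(cov))
        else:
            se = np.zeros(D.shape[1])
        self.n_used_ = len(y)
        self.coef_ = beta[:p]
        self.intercept_ = float(beta[p]) if self.fit_intercept else 0.0
        self.se_ = se[:p]
        self.gamma_, self.tau_, self.delta_ = (float(b) for b in beta[:3])
        self.theta_ = float(beta[3]) if self.model == "M2" else float("nan")
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.resid_ = resid
        return self

    def predict(self, X):
        X = self._validate(X)
        D = _design(X, self.model, self.fit_intercept)
        beta = np.append(self.coef_, self.intercept_) if self.fit_intercept else self.coef_
        return D @ beta


@dataclass
class SensitivityEstimate:
    """Per-window regression result."""

    window_center: object
    window_span: tuple
    model: str
    gamma: float
    tau: float
    delta: float
    theta: float
    r2: float
    n_used: int
    se: dict = field(default_factory=dict)
    boot_sd: dict = field(default_factory=dict)
    resid: np.ndarray | None = None

    def to_row(self) -> dict:
        row = {
            "center": self.window_center, "start": self.window_span[0],
            "end": self.window_span[1], "model": self.model, "gamma": self.gamma,
            "tau": self.tau, "delta": self.delta, "theta": self.theta,
            "r2": self.r2, "n_used": self.n_used,
        }
        for k, v in self.boot_sd.items():
            row[f"{k}_sd"] = v
        return row


def _usable_rows(table: pd.DataFrame) -> pd.DataFrame:
    keep = ~table["excluded"].astype(bool) if "excluded" in table.columns else slice(None)
    rows = table[keep] if "excluded" in table.columns else table
    return rows.dropna(subset=["cgr", *(_REGRESSORS)])


def fit_window(rows: pd.DataFrame, model: str = "M1",
               fit_intercept: bool = True) -> SensitivityEstimate:
    """Fit one sensitivity regression on a joined (cgr, dT, dP, dR) table.

    Rows flagged ``excluded`` (Pinatubo years) are dropped before fitting.
    """
    rows = _usable_rows(rows)
    est = ClimateSensitivityRegression(model=model, fit_intercept=fit_intercept)
    est.fit(rows[list(_REGRESSORS)], rows["cgr"])
    idx = rows.index
    center = idx[len(idx) // 2] if len(idx) else None
    names = _COEF_NAMES[model]
    return SensitivityEstimate(
        window_center=center, window_span=(idx.min(), idx.max()), model=model,
        gamma=est.gamma_, tau=est.tau_, delta=est.delta_, theta=est.theta_,
        r2=est.r2_, n_used=est.n_used_,
        se=dict(zip(names, est.se_)), resid=est.resid_)


def bootstrap_sd(rows: pd.DataFrame, model: str = "M1", reps: int = 500,
                 seed=None, fit_intercept: bool = True,
                 max_skip_frac: float = 0.2) -> dict:
    """Case-resampling bootstrap SD of each coefficient (vectorized).

    Resamples rows with replacement at the original n, refits, and returns the
    SD of each coefficient across replicates. Rank-deficient resamples are
    skipped and counted; more than ``max_skip_frac`` skips is an error.
    """
    rows = _usable_rows(rows)
    X = rows[list(_REGRESSORS)].to_numpy(dtype=float)
    y = rows["cgr"].to_numpy(dtype=float)
    n = len(y)
    D = _design(X, model, fit_intercept)
    _check_rank(D, model, fit_intercept)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    Db = D[idx]                      # (reps, n, k)
    yb = y[idx]                      # (reps, n)
    XtX = np.einsum("rni,rnj->rij", Db, Db)
    Xty = np.einsum("rni,rn->ri", Db, yb)
    # replicates whose resampled design is (near-)singular are skipped
    with np.errstate(all="ignore"):
        good = np.linalg.cond(XtX) < 1e12
    n_skipped = int((~good).sum())
    if n_skipped > max_skip_frac * reps:
        raise RankDeficientError(
            f"{n_skipped}/{reps} bootstrap resamples were rank-deficient")
    beta = np.linalg.solve(XtX[good], Xty[good][..., None])[..., 0]
    p = len(_COEF_NAMES[model])
    sds = beta[:, :p].std(axis=0, ddof=1)
    out = dict(zip(_COEF_NAMES[model], (float(s) for s in sds)))
    out["n_skipped"] = n_skipped
    return out


class MovingWindowSensitivity(BaseEstimator):
    """Moving-window sensitivity estimator over an annual joined table.

    ``fit`` slides a ``window_years`` block (step 1 year) over the table,
    fits the sensitivity regression on the non-excluded rows of each block
    (18 points for blocks covering the 1992–1993 exclusion) and, when
    ``bootstrap_reps > 0``, attaches bootstrap SDs. Windows with too few rows
    are reported as missing with a warning.

    Attributes
    ----------
    estimates_ : pandas.DataFrame
        One row per window: center, start, end, model, gamma, tau, delta,
        theta, r2, n_used and ``*_sd`` bootstrap columns.
    """

    def __init__(self, window_years: int = 20, model: str = "M1",
                 bootstrap_reps: int = 0, random_state=None,
                 fit_intercept: bool = True):
        self.window_years = window_years
        self.model = model
        self.bootstrap_reps = bootstrap_reps
        self.random_state = random_state
        self.fit_intercept = fit_intercept

    def fit(self, table: pd.DataFrame, y=None):
        years = np.asarray(table.index, dtype=int)
        if len(years) < self.window_years:
            raise ValueError("table spans fewer years than the window length")
        first, last = years.min(), years.max()
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        min_n = len(_COEF_NAMES[self.model]) + (2 if self.fit_intercept else 1)
        records = []
        for start in range(first, last - self.window_years + 2):
            end = start + self.window_years - 1
            block = table[(table.index >= start) & (table.index <= end)]
            center = window_center_year(start, self.window_years)
            usable = _usable_rows(block)
            if len(usable) < min_n:
                warnings.warn(f"window {start}-{end}: only {len(usable)} usable rows; "
                              "reported as missing", stacklevel=2)
                records.append({"center": center, "start": start, "end": end,
                                "model": self.model, "gamma": np.nan, "tau": np.nan,
                                "delta": np.nan, "theta": np.nan, "r2": np.nan,
                                "n_used": len(usable)})
                continue
            est = fit_window(block, model=self.model, fit_intercept=self.fit_intercept)
            est.window_center = center
            est.window_span = (start, end)
            if self.bootstrap_reps:
                est.boot_sd = bootstrap_sd(block, model=self.model,
                                           reps=self.bootstrap_reps, seed=rng,
                                           fit_intercept=self.fit_intercept)
                est.boot_sd.pop("n_skipped", None)
            records.append(est.to_row())
        self.estimates_ = pd.DataFrame.from_records(records).set_index("center")
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).estimates_


def moving_window(table: pd.DataFrame, window_years: int = 20, model: str = "M1",
                  bootstrap_reps: int = 0, seed=None) -> pd.DataFrame:
    """Functional wrapper: moving-window gamma estimates as a DataFrame."""
    mws = MovingWindowSensitivity(window_years=window_years, model=model,
                                  bootstrap_reps=bootstrap_reps, random_state=seed)
    return mws.fit(table).estimates_


def highfreq_sensitivity(hf_table: pd.DataFrame, window_months: int = 240,
                         model: str = "M1", step: int = 12,
                         bootstrap_reps: int = 0, seed=None) -> pd.DataFrame:
    """Moving-window sensitivity on the high-frequency (12-month CGR) table.

    ``hf_table`` is indexed by block-center month (PeriodIndex) with columns
    cgr, dT, dP, dR and optional ``excluded``. The fit span is
    ``window_months`` (240 = the 20-year equivalent), advanced by ``step``
    months.
    """
    if not isinstance(hf_table.index, pd.PeriodIndex):
        raise TypeError("high-frequency table must use a monthly PeriodIndex")
    n = len(hf_table)
    if n < window_months:
        raise ValueError("table shorter than the fit window")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for start in range(0, n - window_months + 1, step):
        block = hf_table.iloc[start:start + window_months]
        center = hf_table.index[window_center_position(start, window_months)]
        est = fit_window(block, model=model)
        row = est.to_row()
        row["center"] = center
        row["start"], row["end"] = block.index[0], block.index[-1]
        if bootstrap_reps:
            bs = bootstrap_sd(block, model=model, reps=bootstrap_reps, seed=rng)
            bs.pop("n_skipped", None)
            row.update({f"{k}_sd": v for k, v in bs.items()})
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("center")
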