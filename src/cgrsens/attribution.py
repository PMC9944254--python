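"""Factorial-scenario attribution of changes in the NBP temperature
sensitivity.

A set of factorial land-model runs isolates drivers of the sensitivity
trajectory: SCE1 varies all drivers; SCE2–SCE6 hold exactly one driver
(precipitation, solar radiation, CO2, land use, N deposition) at its
1960–2020 climatology. The sensitivity machinery is applied to -NBP (sign
inverted so uptake anomalies compare directly with the atmospheric growth
rate), trajectories are differenced to expose a driver's contribution, and
continental contributions are decomposed by lmg relative importance
(sequential R^2 averaged over all predictor orderings).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import annual_anomalies, detrend_linear
from .sensitivity import moving_window

SCENARIO_CONSTANT_DRIVER = {
    "SCE1": None,
    "SCE2": "precipitation",
    "SCE3": "solar_radiation",
    "SCE4": "co2",
    "SCE5": "land_use",
    "SCE6": "n_deposition",
}

FLUX_COMPONENTS = ("nbp", "npp", "rh", "fire")


@dataclass
class ScenarioID:
    """Factorial scenario: which driver (if any) is held at climatology."""

    id: str

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_CONSTANT_DRIVER:
            raise ValueError(f"unknown scenario {self.id!r}; "
                             f"expected one of {sorted(SCENARIO_CONSTANT_DRIVER)}")

    @property
    def constant_driver(self) -> str | None:
        return SCENARIO_CONSTANT_DRIVER[self.id]


@dataclass
class FluxSet:
    """Monthly carbon-flux set for one region and scenario.

    ``fluxes`` has columns nbp, npp, rh, fire on a monthly PeriodIndex,
    regional units PgC/y. The identity nbp = npp - rh - fire holds for
    synthetic sets; NBP's sign is inverted whenever it is compared with the
    atmospheric growth rate.
    """

    region: str
    scenario: ScenarioID
    fluxes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FLUX_COMPONENTS if c not in self.fluxes.columns]
        if missing:
            raise ValueError(f"flux table missing columns {missing}")
        if isinstance(self.scenario, str):
            self.scenario = ScenarioID(self.scenario)

    def annual(self) -> pd.DataFrame:
        """Annual-mean fluxes (PgC/y) for complete calendar years."""
        years = self.fluxes.index.year
        counts = self.fluxes.groupby(years).size()
        out = self.fluxes.groupby(years).mean()
        out = out[counts == 12]
        out.index.name = "year"
        return out


def scenario_gamma(fluxset: FluxSet, anomalies: pd.DataFrame, component: str = "nbp",
                   window_years: int = 20, model: str = "M1",
                   bootstrap_reps: int = 0, seed=None,
                   excluded_years=()) -> pd.DataFrame:
    """Moving-window temperature sensitivity of a flux component.

    The component's annual series is sign-inverted for NBP (carbon uptake vs
    atmospheric growth-rate convention), detrended, joined with the climate
    anomalies and passed through the same moving-window regression as the
    growth rate.
    """
    annual = fluxset.annual()
    series = annual[component]
    sign = -1.0 if component == "nbp" else 1.0
    resp = detrend_linear(sign * series)
    table = anomalies.join(pd.DataFrame({"cgr": resp}), how="inner")
    table["excluded"] = np.isin(table.index, list(excluded_years))
    return moving_window(table, window_years=window_years, model=model,
                         bootstrap_reps=bootstrap_reps, seed=seed)


def scenario_difference(traj_a: pd.DataFrame, traj_b: pd.DataFrame,
                        column: str = "gamma") -> pd.DataFrame:
    """Elementwise trajectory difference a - b with propagated bootstrap SD."""
    if not traj_a.index.equals(traj_b.index):
        raise ValueError("trajectories have misaligned window centers")
    out = pd.DataFrame(index=traj_a.index)
    out["diff"] = traj_a[column] - traj_b[column]
    sd_col = f"{column}_sd"
    if sd_col in traj_a.columns and sd_col in traj_b.columns:
        out["diff_sd"] = np.sqrt(traj_a[sd_col] ** 2 + traj_b[sd_col] ** 2)
    return out


@dataclass
class ImportanceShares:
    """lmg decomposition: per-predictor share of explained variance."""

    shares: dict
    total_r2: float

    def __post_init__(self) -> None:
        gap = abs(sum(self.shares.values()) - self.total_r2)
        if gap > 1e-6:
            raise ValueError(f"shares do not sum to R^2 (gap {gap:.2e})")


def _r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...]) -> float:
    D = np.column_stack([X[:, list(cols)], np.ones(len(y))]) if cols else \
        np.ones((len(y), 1))
    beta = np.linalg.lstsq(D, y, rcond=None)[0]
    resid = y - D @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    return 1.0 - float(resid @ resid) / ss_tot


def lmg_importance(y, X, names: list[str] | None = None) -> ImportanceShares:
    """lmg relative importance: average sequential R^2 increment of each
    predictor over all orderings.

    Computed through the equivalent subset (Shapley) weighting
    s!(p-1-s)!/p! over the 2^(p-1) subsets not containing the predictor,
    which enumerates every ordering exactly once. Shares are nonnegative
    up to rounding and sum to the full-model R^2.
    """
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p > 6:
        raise ValueError("exact lmg enumeration supports at most 6 predictors")
    if n <= p + 2:
        raise ValueError("too few observations for the lmg decomposition")
    D = np.column_stack([X, np.ones(n)])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("collinear predictors: lmg is not identified")
    names = names or [f"x{i + 1}" for i in range(p)]

    r2_cache: dict[tuple[int, ...], float] = {}

    def r2_of(cols: tuple[int, ...]) -> float:
        if cols not in r2_cache:
            r2_cache[cols] = _r2(y, X, cols)
        return r2_cache[cols]

    shares = {}
    others = list(range(p))
    for j in range(p):
        rest = [i for i in others if i != j]
        total = 0.0
        for s in range(p):
            w = math.factorial(s) * math.factorial(p - 1 - s) / math.factorial(p)
            for sub in itertools.combinations(rest, s):
                total += w * (r2_of(tuple(sorted(sub + (j,)))) - r2_of(tuple(sorted(sub))))
        shares[names[j]] = total
    return ImportanceShares(shares=shares, total_r2=r2_of(tuple(range(p))))


def flux_component_sensitivity(trend_nbp, trends_npp, trends_rh, trends_fire):
    """Regress gamma_NBP trends on the flux-component sensitivity trends.

    Multiple linear regression (with intercept) of the NBP-sensitivity trends
    on the NPP, Rh and FIRE sensitivity trends; returns a DataFrame of
    coefficients with classical standard errors.
    """
    y = np.asarray(trend_nbp, dtype=float).ravel()
    comps = {"npp": trends_npp, "rh": trends_rh, "fire": trends_fire}
    cols = {}
    for name, series in comps.items():
        arr = np.asarray(series, dtype=float).ravel()
        if len(arr) != len(y):
            raise ValueError(f"trend series '{name}' length mismatch")
        if np.std(arr) == 0:
            raise ValueError(f"zero-variance trend column: '{name}'")
        cols[name] = arr
    if len(y) < 6:
        raise ValueError("need at least 6 aligned trend samples")
    D = np.column_stack(list(cols.values()) + [np.ones(len(y))])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("collinear trend columns")
    beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    dof = len(y) - D.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(D.T @ D)))
    return pd.DataFrame({"coef": beta[:3], "se": se[:3]}, index=list(cols))


def moisture_modulation(fluxset: FluxSet, anomalies: pd.DataFrame,
                        water_state: pd.Series, component: str = "nbp") -> tuple[float, float]:
    """Water-state modulation of the temperature sensitivity (annual scale).

    Fits detrended -NBP on (dT, dP, dR, s*dT) where ``water_state`` s is a
    slow (bi-decadal) standardized water-availability series on the annual
    index. The s*dT coefficient measures how much the temperature sensitivity
    changes per unit of water state — zero when the sensitivity trajectory is
    flat, negative when wet decades weaken it. Estimated on the full annual
    sample, this is a far better-powered flatness diagnostic than trend tests
    on the (heavily serially dependent) window trajectory. Returns
    (coefficient, standard error).
    """
    annual = fluxset.annual()
    sign = -1.0 if component == "nbp" else 1.0
    resp = detrend_linear(sign * annual[component])
    table = anomalies.join(pd.DataFrame({"_y": resp}), how="inner").dropna()
    s = np.asarray(water_state.reindex(table.index), dtype=float)
    if np.any(~np.isfinite(s)):
        raise ValueError("water_state does not cover the joined annual index")
    D = np.column_stack([table["dT"], table["dP"], table["dR"],
                         s * table["dT"], np.ones(len(table))])
    y = table["_y"].to_numpy()
    beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    dof = len(y) - D.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    se = float(np.sqrt(np.diag(sigma2 * np.linalg.inv(D.T @ D)))[3])
    return float(beta[3]), se


def trajectory_correlation(a: pd.Series, b: pd.Series, method: str = "spearman") -> float:
    """Correlation between two aligned sensitivity trajectories."""
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 aligned points")
    return float(joined.corr(method=method).iloc[0, 1])
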