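"""Simulation-based calibration checks of the pipeline on generator truth.

Each function runs the package end to end on synthetic data with known
parameters and returns summary rates or errors: window bookkeeping, unit
conversion, Durbin–Watson calibration, recovery of a rise-and-fall sensitivity
trajectory, size of the random-phase test versus the naive Spearman p-value,
lmg closure, and factorial-scenario attribution. They are what
``scripts/acceptance.py`` reports and what the acceptance test suite asserts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cgr import monthly_cgr, annual_cgr, highfreq_cgr, PPM_TO_PGC
from .climate import annual_anomalies, align, detrend_linear
from .io import StationRecord
from .robust import durbin_watson, mk_prewhitened, random_phase_test, spearman
from .sensitivity import moving_window
from .attribution import (lmg_importance, moisture_modulation, scenario_gamma,
                          scenario_difference)
from .synthetic import (SyntheticTruth, FluxModelParams, gen_climate, gen_co2,
                        gen_flux_scenarios, annual_slow_state,
                        gamma_nbp_window_truth)
from .utils import monthly_period_index


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def count_bookkeeping(seed: int = 0) -> dict:
    """Window and year counts on a default-period synthetic station record."""
    truth = SyntheticTruth(seed=int(seed))
    climate = gen_climate(truth)
    record, _ = gen_co2(truth, climate)
    monthly = monthly_cgr(record)
    hf = highfreq_cgr(monthly)
    ann = annual_cgr(monthly)
    return {
        "monthly_values": int(len(monthly)),
        "highfreq_windows": int(len(hf.values)),
        "annual_years": int(len(ann.values)),
        "annual_usable_years": int(len(ann.usable)),
    }


def conversion_factor_check() -> float:
    """Annual growth rate, in PgC/y, of a record rising exactly 1 ppm/y."""
    idx = monthly_period_index(1959, 12, 37)
    record = StationRecord("ramp", pd.Series(300.0 + np.arange(37) / 12.0, index=idx))
    ann = annual_cgr(monthly_cgr(record))
    vals = ann.values.dropna().to_numpy()
    assert np.allclose(vals, vals[0])
    return float(vals[0])


def dwi_calibration(seed: int = 0, n: int = 10_000, n_vectors: int = 1000) -> dict:
    """Durbin–Watson on iid residuals (expect ~2) and bounds on random vectors."""
    rng = np.random.default_rng(seed)
    mean_dwi = durbin_watson(rng.normal(size=n))
    lo, hi = np.inf, -np.inf
    for _ in range(n_vectors):
        d = durbin_watson(rng.normal(size=int(rng.integers(2, 50))))
        lo, hi = min(lo, d), max(hi, d)
    return {"dwi_iid_mean": float(mean_dwi), "dwi_min": float(lo), "dwi_max": float(hi)}


def run_annual_pipeline(truth: SyntheticTruth, bootstrap_reps: int = 0,
                        seed=None) -> pd.DataFrame:
    """Full station-to-gamma pipeline on one synthetic dataset."""
    climate = gen_climate(truth)
    record, _ = gen_co2(truth, climate)
    ann = annual_cgr(monthly_cgr(record))
    table = align(ann, annual_anomalies(climate.monthly))
    table["cgr"] = detrend_linear(table["cgr"])
    return moving_window(table, bootstrap_reps=bootstrap_reps, seed=seed)


def rise_fall_recovery(n_seeds: int = 100, seed: int = 0) -> dict:
    """Fraction of seeds where the rise-and-fall gamma trajectory is recovered:
    early-half Sen slope positive, late-half negative, both Mann–Kendall
    significant at 0.05."""
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        est = run_annual_pipeline(SyntheticTruth(seed=int(s)))
        g = est["gamma"].to_numpy()
        c = est.index.to_numpy(dtype=float)
        half = len(g) // 2
        early = mk_prewhitened(g[: half + 1], c[: half + 1])
        late = mk_prewhitened(g[half:], c[half:])
        hits += (early.sen_slope > 0 and late.sen_slope < 0
                 and early.mk_p < 0.05 and late.mk_p < 0.05)
    return {"recovery_rate": hits / n_seeds, "n_seeds": n_seeds}


def _ar1_series(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.normal()
    innov = rng.normal(0.0, np.sqrt(1 - phi * phi), size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i - 1]
    return x


def random_phase_type1(n_pairs: int = 500, n: int = 60, phi: float = 0.7,
                       reps: int = 1000, seed: int = 0) -> dict:
    """Type-I error of the random-phase test on independent AR(1) pairs,
    against the naive Spearman p-value on the same data."""
    rng = np.random.default_rng(seed)
    surrogate_rej = naive_rej = 0
    for _ in range(n_pairs):
        x = _ar1_series(rng, n, phi)
        y = _ar1_series(rng, n, phi)
        p, _ = random_phase_test(x, y, reps=reps, seed=rng)
        surrogate_rej += p < 0.05
        naive_rej += spearman(x, y)[1] < 0.05
    return {
        "random_phase_rejection_rate": surrogate_rej / n_pairs,
        "naive_spearman_rejection_rate": naive_rej / n_pairs,
        "n_pairs": n_pairs,
    }


def lmg_closure(n_designs: int = 100, seed: int = 0) -> dict:
    """Closure (shares sum to R^2) on random designs and agreement with the
    direct enumeration over all 3! orderings for three predictors."""
    import itertools

    rng = np.random.default_rng(seed)
    max_gap = 0.0
    max_dev = 0.0
    for _ in range(n_designs):
        n, p = 30, 3
        X = rng.normal(size=(n, p)) @ (np.eye(p) + rng.normal(0, 0.3, (p, p)))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        imp = lmg_importance(y, X)
        max_gap = max(max_gap, abs(sum(imp.shares.values()) - imp.total_r2))

        def r2(cols):
            D = (np.column_stack([X[:, list(cols)], np.ones(n)])
                 if cols else np.ones((n, 1)))
            beta = np.linalg.lstsq(D, y, rcond=None)[0]
            resid = y - D @ beta
            return 1 - (resid @ resid) / np.sum((y - y.mean()) ** 2)

        shares = np.zeros(p)
        orders = list(itertools.permutations(range(p)))
        for order in orders:
            done, prev = [], 0.0
            for j in order:
                cur = r2(tuple(sorted(done + [j])))
                shares[j] += cur - prev
                prev, done = cur, done + [j]
        shares /= len(orders)
        max_dev = max(max_dev, float(np.max(np.abs(
            np.array(list(imp.shares.values())) - shares))))
    return {"lmg_max_closure_gap": max_gap, "lmg_max_enumeration_dev": max_dev,
            "n_designs": n_designs}


def scenario_attribution(n_seeds: int = 50, seed: int = 0,
                         bootstrap_reps: int = 500) -> dict:
    """Factorial-scenario check on generator truth.

    Per seed: (i) the water modulation of the temperature sensitivity is
    detected in the full run (SCE1) and absent with precipitation held at
    climatology (SCE2) — interaction coefficients classified by nearest truth
    (-gamma_moist vs 0); (ii) the SCE1-SCE2 trajectory difference covers the
    injected precipitation-driven component in >= 80% of window CIs.
    """
    params = FluxModelParams()
    flat_hits = vary_hits = cover_hits = joint = 0
    for k, s in enumerate(_child_seeds(seed, n_seeds)):
        truth = SyntheticTruth(seed=int(s))
        climate = gen_climate(truth)
        fx = gen_flux_scenarios(truth, climate, scenarios=("SCE1", "SCE2"))
        anoms = annual_anomalies(climate.monthly)
        state = annual_slow_state(truth)
        m1, _ = moisture_modulation(fx["SCE1"]["tropics"], anoms, state)
        m2, _ = moisture_modulation(fx["SCE2"]["tropics"], anoms, state)
        midpoint = -params.gamma_moist / 2.0
        varies = m1 < midpoint
        flat = m2 > midpoint
        t1 = scenario_gamma(fx["SCE1"]["tropics"], anoms,
                            bootstrap_reps=bootstrap_reps, seed=int(s))
        t2 = scenario_gamma(fx["SCE2"]["tropics"], anoms,
                            bootstrap_reps=bootstrap_reps, seed=int(s) // 2 + 1)
        diff = scenario_difference(t1, t2)
        injected = (gamma_nbp_window_truth(truth, params)
                    - gamma_nbp_window_truth(truth, params, constant_precip=True))
        coverage = float(((diff["diff"] - injected).abs()
                          <= 1.96 * diff["diff_sd"]).mean())
        covered = coverage >= 0.8
        flat_hits += flat
        vary_hits += varies
        cover_hits += covered
        joint += flat and varies and covered
    return {
        "sce2_flat_rate": flat_hits / n_seeds,
        "sce1_varies_rate": vary_hits / n_seeds,
        "difference_coverage_rate": cover_hits / n_seeds,
        "scenario_joint_rate": joint / n_seeds,
        "n_seeds": n_seeds,
    }
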