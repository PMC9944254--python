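import numpy as np
import pandas as pd
import pytest

import cgrsens as cs
from cgrsens.sensitivity import RankDeficientError
from conftest import make_anomaly_frame


def joined(X, cgr, excluded=None):
    table = X.copy()
    table["cgr"] = cgr
    table["excluded"] = False if excluded is None else excluded
    return table


class TestFitWindow:
    def test_noiseless_recovery(self, rng):
        X = make_anomaly_frame(rng)
        cgr = 3.0 * X["dT"] + 0.5 * X["dP"] - 1.0 * X["dR"]
        est = cs.fit_window(joined(X, cgr), model="M1")
        assert est.gamma == pytest.approx(3.0, abs=1e-10)
        assert est.tau == pytest.approx(0.5, abs=1e-10)
        assert est.delta == pytest.approx(-1.0, abs=1e-10)
        assert est.r2 == pytest.approx(1.0, abs=1e-12)

    def test_m2_nests_m1_on_interaction_free_data(self, rng):
        X = make_anomaly_frame(rng)
        cgr = 3.0 * X["dT"] + 0.5 * X["dP"] - 1.0 * X["dR"]
        est = cs.fit_window(joined(X, cgr), model="M2")
        assert est.theta == pytest.approx(0.0, abs=1e-8)
        assert est.gamma == pytest.approx(3.0, abs=1e-8)

    def test_m2_matches_normal_equations_oracle(self, rng):
        X = make_anomaly_frame(rng)
        cgr = (2.0 * X["dT"] - 0.01 * X["dP"] + 0.3 * X["dR"]
               + 0.8 * X["dT"] * X["dP"] + rng.normal(0, 0.1, len(X)))
        est = cs.fit_window(joined(X, cgr), model="M2")
        D = np.column_stack([X["dT"], X["dP"], X["dR"], X["dT"] * X["dP"],
                             np.ones(len(X))])
        beta = np.linalg.inv(D.T @ D) @ D.T @ cgr.to_numpy()
        np.testing.assert_allclose(
            [est.gamma, est.tau, est.delta, est.theta], beta[:4], atol=1e-10)

    def test_excluded_rows_are_dropped(self, rng):
        X = make_anomaly_frame(rng)
        cgr = 2.0 * X["dT"]
        excl = np.zeros(len(X), dtype=bool)
        excl[3] = True
        table = joined(X, cgr, excl)
        table.loc[table.index[3], "cgr"] = 99.0  # poisoned excluded row
        est = cs.fit_window(table)
        assert est.gamma == pytest.approx(2.0, abs=1e-10)
        assert est.n_used == len(X) - 1

    def test_collinear_design_raises(self, rng):
        X = make_anomaly_frame(rng)
        X["dR"] = 2.0 * X["dT"]
        with pytest.raises(RankDeficientError, match="collinear"):
            cs.fit_window(joined(X, 1.0 * X["dT"]))

    def test_unit_equivariance(self, rng):
        X = make_anomaly_frame(rng)
        cgr = 3.0 * X["dT"] + 0.5 * X["dP"] - 1.0 * X["dR"] + rng.normal(0, 0.2, len(X))
        est1 = cs.fit_window(joined(X, cgr))
        X2 = X.copy()
        X2["dT"] = 10.0 * X["dT"]
        est2 = cs.fit_window(joined(X2, cgr))
        assert est2.gamma == pytest.approx(est1.gamma / 10.0, rel=1e-10)
        assert est2.r2 == pytest.approx(est1.r2, rel=1e-12)


class TestEstimatorProtocol:
    def test_get_set_params_and_predict(self, rng):
        X = make_anomaly_frame(rng)
        y = 1.5 * X["dT"] + 0.1
        reg = cs.ClimateSensitivityRegression(model="M1")
        assert reg.get_params()["model"] == "M1"
        reg.set_params(model="M2").fit(X, y)
        np.testing.assert_allclose(reg.predict(X), y, atol=1e-8)
        assert reg.intercept_ == pytest.approx(0.1, abs=1e-8)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        reg = cs.ClimateSensitivityRegression(model="M2", fit_intercept=False)
        c = clone(reg)
        assert c.model == "M2" and c.fit_intercept is False


class TestMovingWindow:
    def test_42_windows_with_correct_spans(self, annual_table):
        est = cs.moving_window(annual_table)
        assert len(est) == 42
        assert est.index[0] == 1970 and est.index[-1] == 2011
        assert (est["start"].iloc[0], est["end"].iloc[0]) == (1960, 1979)
        assert (est["start"].iloc[-1], est["end"].iloc[-1]) == (2001, 2020)

    def test_pinatubo_windows_fit_on_18_points(self, annual_table):
        est = cs.moving_window(annual_table)
        expected = [20 - sum(1 for y in (1992, 1993) if s <= y <= e)
                    for s, e in zip(est["start"], est["end"])]
        assert est["n_used"].tolist() == expected
        assert (est["n_used"] == 18).sum() == 19  # spans covering both years

    def test_constant_truth_recovered_within_ci(self):
        truth = cs.SyntheticTruth(seed=11, gamma_knots=((1960.0, 2.0), (2020.0, 2.0)),
                                  noise_sd=0.2)
        clim = cs.gen_climate(truth)
        rec, _ = cs.gen_co2(truth, clim)
        ann = cs.annual_cgr(cs.monthly_cgr(rec))
        table = cs.align(ann, cs.annual_anomalies(clim.monthly))
        table["cgr"] = cs.detrend_linear(table["cgr"])
        est = cs.moving_window(table, bootstrap_reps=200, seed=0)
        cover = ((est["gamma"] - 2.0).abs() <= 1.96 * est["gamma_sd"]).mean()
        assert cover >= 0.8

    def test_rise_fall_truth_flips_sen_slope_sign(self, annual_table):
        est = cs.moving_window(annual_table)
        g = est["gamma"].to_numpy()
        half = len(g) // 2
        assert cs.theil_sen(g[: half + 1]) > 0
        assert cs.theil_sen(g[half:]) < 0

    def test_short_table_raises(self, annual_table):
        with pytest.raises(ValueError):
            cs.moving_window(annual_table.iloc[:10])


class TestBootstrap:
    def test_zero_variance_limit(self, rng):
        X = make_anomaly_frame(rng)
        cgr = 3.0 * X["dT"] + 0.5 * X["dP"] - 1.0 * X["dR"]
        sds = cs.bootstrap_sd(joined(X, cgr), reps=100, seed=0)
        assert all(sds[k] <= 1e-8 for k in ("gamma", "tau", "delta"))

    def test_seed_determinism(self, rng):
        X = make_anomaly_frame(rng)
        cgr = 3.0 * X["dT"] + rng.normal(0, 1.0, len(X))
        a = cs.bootstrap_sd(joined(X, cgr), reps=200, seed=123)
        b = cs.bootstrap_sd(joined(X, cgr), reps=200, seed=123)
        assert a == b

    def test_sd_tracks_analytic_standard_error(self):
        r = np.random.default_rng(5)
        X = make_anomaly_frame(None, n=20, seed=5)
        cgr = 3.0 * X["dT"] + r.normal(0, 1.0, len(X))
        table = joined(X, cgr)
        est = cs.fit_window(table)
        sds = cs.bootstrap_sd(table, reps=500, seed=7)
        assert sds["gamma"] == pytest.approx(est.se["gamma"], rel=0.25)


class TestParameterRecovery:
    def test_mean_gamma_within_5pct_and_boot_sd_calibrated(self):
        """Direct-regression recovery at n=20, noise at half the signal SD."""
        gammas, boot_sds = [], []
        truth_gamma = 3.0
        for seed in range(200):
            r = np.random.default_rng(10_000 + seed)  # independent of the design
            X = make_anomaly_frame(None, n=20, seed=seed)
            signal = truth_gamma * X["dT"] + 0.01 * X["dP"] - 0.2 * X["dR"]
            noise_sd = 0.5 * signal.std()
            table = joined(X, signal + r.normal(0, noise_sd, len(X)))
            gammas.append(cs.fit_window(table).gamma)
            boot_sds.append(cs.bootstrap_sd(table, reps=200, seed=seed)["gamma"])
        gammas = np.asarray(gammas)
        assert abs(gammas.mean() - truth_gamma) / truth_gamma < 0.05
        assert abs(np.mean(boot_sds) - gammas.std()) / gammas.std() < 0.30


class TestHighfreqSensitivity:
    def test_constant_gamma_trajectory_statistically_flat(self):
        truth = cs.SyntheticTruth(seed=21, gamma_knots=((1960.0, 2.5), (2020.0, 2.5)))
        clim = cs.gen_climate(truth)
        rec, _ = cs.gen_co2(truth, clim)
        hf = cs.highfreq_cgr(cs.monthly_cgr(rec))
        roll = clim.monthly.rolling(12).mean().iloc[11:]
        roll.index = clim.monthly.index[5:5 + len(roll)]
        table = pd.DataFrame({"cgr": cs.detrend_linear(hf.values)})
        table["dT"] = cs.detrend_linear(roll["T"].reindex(table.index))
        table["dP"] = cs.detrend_linear(12.0 * roll["P"].reindex(table.index))
        table["dR"] = cs.detrend_linear(roll["R"].reindex(table.index))
        est = cs.highfreq_sensitivity(table, window_months=240, step=12)
        assert len(est) == (721 - 240) // 12 + 1
        g = est["gamma"].to_numpy()
        # the pooled fit over all 721 points pins the constant truth tightly;
        # the window trajectory wanders with its (correlated) estimation noise
        pooled = cs.fit_window(table)
        assert pooled.gamma == pytest.approx(2.5, abs=0.5)
        assert np.percentile(np.abs(g - 2.5), 90) < 1.2
        assert g.std() < 0.6

    def test_annual_and_highfreq_gamma_agree(self, truth, climate, station, annual_table):
        record, _ = station
        hf = cs.highfreq_cgr(cs.monthly_cgr(record))
        roll = climate.monthly.rolling(12).mean().iloc[11:]
        roll.index = climate.monthly.index[5:5 + len(roll)]
        table = pd.DataFrame({"cgr": cs.detrend_linear(hf.values)})
        table["dT"] = cs.detrend_linear(roll["T"].reindex(table.index))
        table["dP"] = cs.detrend_linear(12.0 * roll["P"].reindex(table.index))
        table["dR"] = cs.detrend_linear(roll["R"].reindex(table.index))
        hf_est = cs.highfreq_sensitivity(table, window_months=240, step=12)
        ann_est = cs.moving_window(annual_table)
        hf_by_year = hf_est["gamma"].groupby(hf_est.index.year).mean()
        common = ann_est.index.intersection(hf_by_year.index)
        r = np.corrcoef(ann_est.loc[common, "gamma"], hf_by_year.loc[common])[0, 1]
        assert r > 0.8
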