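"""Synthetic inputs with recorded ground truth.

The generator emulates the statistical structure the analysis assumes, so
every estimator in the package can be checked against known parameters:

* tropical climate anomalies with ENSO-like AR(1) persistence, a slow
  ("bi-decadal") sinusoidal modulation of precipitation that is driest around
  1990, and radiation anomalies weakly anti-correlated with precipitation;
* a station CO2 record built by inverting the sensitivity model itself —
  a monthly growth rate gamma(t)*dT + tau*dP + delta*dR (+ theta*dT*dP) + eps
  is integrated to concentrations (via the 2.124 PgC/ppm factor) and a
  seasonal cycle is added on top, which cancels in 12-month differences;
* factorial-scenario flux sets (SCE1–SCE6) from a minimal response model in
  which NPP gains from precipitation, CO2, N deposition and land use, Rh
  rises with temperature at a rate modulated by the slow precipitation state
  (the mechanism that makes gamma_NBP water-dependent), and FIRE spikes only
  in very dry months; NBP = NPP - Rh - FIRE by construction.

The default period is Jan 1960–Dec 2020 (732 months, with a Dec 1959 lead
concentration) so the bookkeeping counts of the real analysis (721
high-frequency windows, 59 usable years) hold on synthetic data. Every draw
comes from named child streams of one seed, so outputs are byte-identical
across runs with the same truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .cgr import PPM_TO_PGC
from .io import StationRecord
from .attribution import FluxSet, ScenarioID, SCENARIO_CONSTANT_DRIVER
from .utils import monthly_period_index, window_center_year


@dataclass
class SyntheticTruth:
    """Generator parameters; serialized alongside every generated dataset.

    ``gamma_knots`` defines a piecewise-linear temperature sensitivity of the
    growth rate in PgC/y/K. A 20-year boxcar attenuates the underlying swing,
    so the default knots (0.4 -> 6.4 over 1960-1990, falling to 0.8 by 2020)
    are chosen such that the *window-mean* trajectory — what the moving-window
    regression actually estimates — rises from about 2.4 to 5.4 and falls back
    to 2.5, i.e. reproduces the magnitude and the roughly +-0.15 PgC/y/K per
    year trends of the observed window estimates. Noise and persistence
    defaults are observation-like: annual-equivalent regression noise at
    roughly half the climate-driven signal SD, monthly temperature anomalies
    with lag-1 persistence 0.5.
    """

    gamma_knots: tuple = ((1960.0, 0.4), (1990.0, 6.4), (2020.0, 0.8))
    tau_true: float = -0.005        # PgC/y per mm/y
    delta_true: float = -0.05       # PgC/y per W/m^2
    theta_true: float = 0.0         # PgC/y per (K * mm/y)
    ar1_temp: float = 0.5           # monthly lag-1 coefficient
    ar1_precip: float = 0.3
    ar1_rad: float = 0.3
    temp_sd: float = 0.3            # K, monthly anomaly SD
    precip_sd: float = 72.0         # mm/y rate, monthly anomaly SD
    rad_sd: float = 1.5             # W/m^2, monthly anomaly SD
    rad_precip_corr: float = -0.4
    precip_bidecadal_amplitude: float = 40.0  # mm/y
    precip_bidecadal_period: float = 60.0     # years (one trough, at 1990)
    precip_bidecadal_trough: float = 1990.0
    noise_sd: float = 0.25          # PgC/y, annual-equivalent
    trend_co2: float = 1.5          # ppm/y
    seasonal_amplitude: float = 3.0  # ppm
    co2_baseline: float = 315.0     # ppm at the lead month
    temp_clim: float = 25.0         # deg C
    precip_clim: float = 1400.0     # mm/y
    rad_clim: float = 200.0         # W/m^2
    start_year: int = 1960
    n_years: int = 61
    pinatubo: bool = False
    pinatubo_depletion: float = 1.5  # PgC/y drawn down in 1992-1993
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ar1_temp", "ar1_precip", "ar1_rad"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1 for stationarity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_years < 25:
            raise ValueError("need at least 25 years for the moving-window analysis")

    # piecewise-linear gamma(t)
    def gamma(self, t):
        knots = np.asarray(self.gamma_knots, dtype=float)
        return np.interp(np.asarray(t, dtype=float), knots[:, 0], knots[:, 1])

    def slow_precip(self, t):
        """Injected bi-decadal precipitation component (mm/y)."""
        t = np.asarray(t, dtype=float)
        return -self.precip_bidecadal_amplitude * np.cos(
            2.0 * np.pi * (t - self.precip_bidecadal_trough)
            / self.precip_bidecadal_period)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["gamma_knots"] = tuple(tuple(k) for k in d["gamma_knots"])
        return cls(**d)


@dataclass
class ClimateFields:
    """Generated tropical climate: monthly means plus the anomaly components
    actually injected (dT, dP as an mm/y rate, dR, and the slow precipitation
    state), and optionally a small gridded version."""

    monthly: pd.DataFrame                 # columns T (degC), P (mm/month), R (W/m^2)
    components: pd.DataFrame              # columns dT, dP, dR, p_slow
    truth: SyntheticTruth
    grid: xr.Dataset | None = None


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) draw with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _year_frac(index: pd.PeriodIndex) -> np.ndarray:
    return index.year.to_numpy() + (index.month.to_numpy() - 0.5) / 12.0


def gen_climate(truth: SyntheticTruth, n_years: int | None = None,
                grid: tuple[int, int] | None = None) -> ClimateFields:
    """Generate monthly tropical-mean climate (and optionally a small grid).

    Temperature and radiation anomalies are AR(1); precipitation is a
    climatology (with a mild seasonal cycle summing to the annual total) plus
    AR(1) anomalies plus the slow bi-decadal component. Radiation anomalies
    are anti-correlated with precipitation anomalies (cloudier wet spells).
    """
    n_years = n_years or truth.n_years
    n = 12 * n_years
    idx = monthly_period_index(truth.start_year, 1, n)
    t = _year_frac(idx)
    ss = np.random.SeedSequence(truth.seed)
    rng_t, rng_p, rng_r, rng_g = (np.random.default_rng(c) for c in ss.spawn(4))

    dT = _ar1(rng_t, n, truth.ar1_temp, truth.temp_sd)
    dP = _ar1(rng_p, n, truth.ar1_precip, truth.precip_sd)        # mm/y rate
    z = _ar1(rng_r, n, truth.ar1_rad, truth.rad_sd)
    c = truth.rad_precip_corr
    dR = (c * (dP / truth.precip_sd) * truth.rad_sd
          + np.sqrt(max(0.0, 1.0 - c * c)) * z) if truth.precip_sd > 0 else z
    p_slow = truth.slow_precip(t)

    month = idx.month.to_numpy()
    seasonal_p = 1.0 + 0.3 * np.sin(2.0 * np.pi * (month - 1) / 12.0)
    P = (truth.precip_clim * seasonal_p + p_slow + dP) / 12.0      # mm/month
    T = truth.temp_clim + dT
    R = truth.rad_clim + dR

    monthly = pd.DataFrame({"T": T, "P": P, "R": R}, index=idx)
    components = pd.DataFrame({"dT": dT, "dP": dP, "dR": dR, "p_slow": p_slow},
                              index=idx)

    grid_ds = None
    if grid is not None:
        nlat, nlon = grid
        lat = np.linspace(-20.0, 20.0, nlat)
        lon = np.linspace(-150.0, 150.0, nlon)
        # spatially varying long-term means, shared temporal anomalies,
        # small independent pixel noise
        p_offset = rng_g.normal(0.0, 300.0, size=(nlat, nlon))      # mm/y
        t_offset = rng_g.normal(0.0, 1.5, size=(nlat, nlon))        # K
        px_noise = rng_g.normal(0.0, 0.05, size=(n, nlat, nlon))
        temp = T[:, None, None] + t_offset[None] + px_noise
        precip = np.clip(P[:, None, None] + p_offset[None] / 12.0
                         + 2.0 * px_noise, 0.0, None)
        rad = R[:, None, None] + 0.5 * px_noise
        mask = np.ones((nlat, nlon), dtype=np.int8)
        mask[0, 0] = 0  # one ocean cell so masking is exercised
        times = pd.date_range(f"{truth.start_year}-01-01", periods=n, freq="MS")
        grid_ds = xr.Dataset(
            {
                "temp": (("time", "lat", "lon"), temp),
                "precip": (("time", "lat", "lon"), precip),
                "rad": (("time", "lat", "lon"), rad),
                "mask": (("lat", "lon"), mask),
            },
            coords={"time": times, "lat": lat, "lon": lon},
            attrs={"title": "synthetic tropical climate", "Conventions": "CF-1.8"},
        )
    return ClimateFields(monthly=monthly, components=components, truth=truth,
                         grid=grid_ds)


def gen_co2(truth: SyntheticTruth, climate: ClimateFields) -> tuple[StationRecord, pd.Series]:
    """Station CO2 record whose growth rate follows the sensitivity model.

    The monthly growth-rate anomaly a_m = gamma(t)*dT + tau*dP + delta*dR
    (+ theta*dT*dP) + eps (PgC/y) is converted to monthly ppm increments
    (adding the secular trend), cumulatively summed from the baseline at the
    lead month (December before the start year), and a seasonal cycle is
    superposed. Returns the record and the constructed annual growth-rate
    truth in PgC/y, which ``annual_cgr`` recovers to rounding error.
    """
    comp = climate.components
    if len(comp) != 12 * truth.n_years:
        raise ValueError("climate span does not match the requested record")
    idx = comp.index
    t = _year_frac(idx)
    ss = np.random.SeedSequence(truth.seed)
    rng_e = np.random.default_rng(ss.spawn(5)[4])

    gam = truth.gamma(t)
    # the growth rate responds to the full precipitation anomaly: fast AR(1)
    # variability plus the slow bi-decadal component
    dP_total = comp["dP"].to_numpy() + comp["p_slow"].to_numpy()
    a = (gam * comp["dT"].to_numpy()
         + truth.tau_true * dP_total
         + truth.delta_true * comp["dR"].to_numpy()
         + truth.theta_true * comp["dT"].to_numpy() * dP_total)
    a = a + rng_e.normal(0.0, truth.noise_sd * np.sqrt(12.0), size=len(a))
    if truth.pinatubo:
        a = a - truth.pinatubo_depletion * np.isin(idx.year, (1992, 1993))

    d_ppm = truth.trend_co2 / 12.0 + a / (12.0 * PPM_TO_PGC)       # ppm/month

    lead = pd.Period(f"{truth.start_year - 1}-12", freq="M")
    full_idx = monthly_period_index(truth.start_year - 1, 12, len(idx) + 1)
    levels = truth.co2_baseline + np.concatenate([[0.0], np.cumsum(d_ppm)])
    months = full_idx.month.to_numpy()
    seasonal = truth.seasonal_amplitude * np.cos(2.0 * np.pi * (months - 5) / 12.0)
    record = StationRecord(
        station_id="synthetic",
        data=pd.Series(levels + seasonal, index=full_idx, name="co2"))

    annual_truth = (pd.Series(d_ppm, index=idx).groupby(idx.year).sum()
                    * PPM_TO_PGC)
    annual_truth.name = "cgr_truth_pgc"
    return record, annual_truth


def gamma_window_truth(truth: SyntheticTruth, window_years: int = 20) -> pd.Series:
    """Window-mean true gamma at each moving-window center."""
    years = np.arange(truth.start_year, truth.start_year + truth.n_years)
    # annual-mean gamma from monthly interpolation
    gam_ann = np.array([truth.gamma(y + (np.arange(12) + 0.5) / 12.0).mean()
                        for y in years])
    out = {}
    for s in range(len(years) - window_years + 1):
        center = window_center_year(int(years[s]), window_years)
        out[center] = gam_ann[s:s + window_years].mean()
    return pd.Series(out, name="gamma_truth")


# --- factorial-scenario flux generation -------------------------------------

@dataclass
class FluxModelParams:
    """Coefficients of the minimal flux response model (tropics total, PgC/y)."""

    npp0: float = 60.0
    rh0: float = 55.0
    fire0: float = 2.0
    k_npp_t: float = 1.0      # PgC/y per K (NPP declines with warming)
    k_npp_p: float = 0.004    # PgC/y per mm/y
    k_npp_r: float = 0.05     # PgC/y per W/m^2
    k_npp_co2: float = 0.1    # PgC/y per ppm
    k_rh0: float = 2.2        # PgC/y per K, baseline Rh temperature response
    gamma_moist: float = 1.6  # modulation of the Rh response by the slow
                              # precipitation state (wet -> weaker response)
    fire_spike: float = 0.8   # PgC/y added in very dry months
    lu_decline: float = 0.001  # fractional NPP-capacity loss per year
    ndep_gain: float = 0.1    # fractional NPP gain at full N-deposition ramp
    noise_sd: float = 0.2     # PgC/y annual-equivalent, per flux component

    def gamma_nbp(self, s_norm) -> np.ndarray:
        """True temperature sensitivity of -NBP given the slow precip state."""
        return self.k_npp_t + self.k_rh0 - self.gamma_moist * np.asarray(s_norm)


DEFAULT_REGION_WEIGHTS = {"AF": 0.5, "AA": 0.3, "SA": 0.2}
# continental share of the moisture modulation (weighted sum = 1, Africa
# dominant, matching the continental ordering the attribution should recover)
REGION_MOISTURE_SCALE = {"AF": 1.52, "AA": 0.6, "SA": 0.3, "tropics": 1.0}


def _monthly_climatology(series: pd.Series) -> pd.Series:
    clim = series.groupby(series.index.month).mean()
    return pd.Series(clim.loc[series.index.month].to_numpy(), index=series.index)


def gen_flux_scenarios(truth: SyntheticTruth, climate: ClimateFields,
                       scenarios=("SCE1", "SCE2"), regions=("tropics",),
                       params: FluxModelParams | None = None) -> dict:
    """Factorial flux sets: {scenario: {region: FluxSet}}.

    For SCE2–SCE6 the named driver is replaced by its full-period monthly
    climatology (annual mean for CO2 and land use) before the response model
    runs; everything else varies. The temperature sensitivity of NBP is made
    water-dependent through the slow precipitation state, so holding
    precipitation constant (SCE2) freezes the gamma_NBP trajectory — the
    mechanism under study.
    """
    params = params or FluxModelParams()
    monthly = climate.monthly
    idx = monthly.index
    n = len(idx)
    t = _year_frac(idx)
    region_list = list(regions)
    # one independent stream per (scenario, region): outputs do not depend on
    # which other scenarios were requested
    sce_order = list(SCENARIO_CONSTANT_DRIVER)
    pool = np.random.SeedSequence(truth.seed).spawn(10 + 6 * 8)
    child = {(s, r): np.random.default_rng(pool[10 + 8 * sce_order.index(s) + k])
             for s in sce_order for k, r in enumerate(region_list)}

    # time-varying drivers
    co2 = truth.co2_baseline + truth.trend_co2 * (t - truth.start_year)
    lu = 1.0 - params.lu_decline * (t - truth.start_year)
    nd = (t - truth.start_year) / truth.n_years

    out: dict[str, dict[str, FluxSet]] = {}
    for sce in scenarios:
        const = SCENARIO_CONSTANT_DRIVER.get(sce)
        if sce not in SCENARIO_CONSTANT_DRIVER:
            raise ValueError(f"unknown scenario {sce!r}")
        P = monthly["P"].copy()
        R = monthly["R"].copy()
        co2_s, lu_s, nd_s = co2.copy(), lu.copy(), nd.copy()
        p_slow = climate.components["p_slow"].to_numpy().copy()
        if const == "precipitation":
            P = _monthly_climatology(P)
            p_slow = np.zeros(n)
        elif const == "solar_radiation":
            R = _monthly_climatology(R)
        elif const == "co2":
            co2_s = np.full(n, co2.mean())
        elif const == "land_use":
            lu_s = np.full(n, lu.mean())
        elif const == "n_deposition":
            nd_s = np.full(n, nd.mean())

        dT = monthly["T"] - _monthly_climatology(monthly["T"])
        dP = 12.0 * (P - _monthly_climatology(P))                   # mm/y rate
        dR = R - _monthly_climatology(R)
        s_norm = p_slow / truth.precip_bidecadal_amplitude
        sigma_p = np.zeros(n)
        if float(dP.std()) > 0:
            sigma_p = (dP / dP.std(ddof=0)).to_numpy()

        sd_m = params.noise_sd * np.sqrt(12.0)
        sets: dict[str, FluxSet] = {}
        total = None
        for region in region_list:
            if region == "tropics" and len(region_list) > 1:
                continue
            w = DEFAULT_REGION_WEIGHTS.get(region, 1.0)
            k_rh = (params.k_rh0
                    - params.gamma_moist * REGION_MOISTURE_SCALE.get(region, 1.0)
                    * s_norm)
            rng = child[(sce, region)]
            npp = w * (params.npp0 * lu_s * (1.0 + params.ndep_gain * nd_s)
                       + params.k_npp_co2 * (co2_s - truth.co2_baseline)
                       + params.k_npp_p * dP.to_numpy()
                       + params.k_npp_r * dR.to_numpy()
                       - params.k_npp_t * dT.to_numpy())
            rh = w * (params.rh0 + k_rh * dT.to_numpy())
            fire = w * (params.fire0 + params.fire_spike * (sigma_p < -1.0))
            npp = npp + w * rng.normal(0.0, sd_m, size=n)
            rh = rh + w * rng.normal(0.0, sd_m, size=n)
            flux = pd.DataFrame({"npp": npp, "rh": rh, "fire": fire}, index=idx)
            flux["nbp"] = flux["npp"] - flux["rh"] - flux["fire"]
            sets[region] = FluxSet(region=region, scenario=ScenarioID(sce),
                                   fluxes=flux[list(("nbp", "npp", "rh", "fire"))])
            total = flux if total is None else total + flux
        if "tropics" not in sets and total is not None:
            total["nbp"] = total["npp"] - total["rh"] - total["fire"]
            sets["tropics"] = FluxSet(region="tropics", scenario=ScenarioID(sce),
                                      fluxes=total[list(("nbp", "npp", "rh", "fire"))])
        out[sce] = sets
    return out


def annual_slow_state(truth: SyntheticTruth, years=None) -> pd.Series:
    """Annual-mean injected bi-decadal precipitation state, standardized to
    the generator's amplitude (so it spans about -1..1)."""
    if years is None:
        years = np.arange(truth.start_year, truth.start_year + truth.n_years)
    years = np.asarray(years, dtype=int)
    s = np.array([truth.slow_precip(y + (np.arange(12) + 0.5) / 12.0).mean()
                  for y in years]) / truth.precip_bidecadal_amplitude
    return pd.Series(s, index=pd.Index(years, name="year"), name="s_state")


def gamma_nbp_window_truth(truth: SyntheticTruth, params: FluxModelParams,
                           window_years: int = 20,
                           constant_precip: bool = False) -> pd.Series:
    """Window-mean true gamma_NBP trajectory for a scenario."""
    years = np.arange(truth.start_year, truth.start_year + truth.n_years)
    if constant_precip:
        s_ann = np.zeros(len(years))
    else:
        s_ann = np.array([
            truth.slow_precip(y + (np.arange(12) + 0.5) / 12.0).mean()
            for y in years]) / truth.precip_bidecadal_amplitude
    g_ann = params.gamma_nbp(s_ann)
    out = {}
    for s in range(len(years) - window_years + 1):
        center = window_center_year(int(years[s]), window_years)
        out[center] = g_ann[s:s + window_years].mean()
    return pd.Series(out, name="gamma_nbp_truth")
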