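# Methods

## The model

The atmospheric CO₂ growth rate (CGR) is the first-order difference of
monthly station CO₂ concentration. The backward difference for month *m* is
assigned to *m*, so the calendar-year sum telescopes to the
December-to-December concentration change, and a record with a lead month
(December of the year before the analysis start) yields, for 1960–2020, 732
monthly growth-rate values, 721 sliding 12-month windows and 61 annual
values. Conversion from ppm to carbon mass uses 2.124 PgC ppm⁻¹. The years
1992–1993 are flagged (not deleted): the Mt Pinatubo eruption perturbs the
growth rate through diffuse-light, radiation, precipitation and temperature
effects that the climate regressors do not capture. Flagged years are
excluded from every fit, leaving 59 usable annual values.

The temperature sensitivity γ is the ΔT coefficient of an OLS regression of
growth-rate anomalies on detrended tropical climate anomalies,

    M1:  CGR = γ ΔT + τ ΔP + δ ΔR + ε
    M2:  CGR = γ ΔT + τ ΔP + δ ΔR + θ (ΔT × ΔP) + ε

fitted inside each 20-calendar-year moving window (step one year; windows
covering 1992–1993 fit on 18 points). Anomalies are residuals around the
*full-period* OLS line, computed once, not per window — per-window
detrending would change γ and is deliberately not the default. Because
sub-period means of full-period anomalies are not zero, every fit includes
an intercept. Windows are labeled by the center year (start + 10); the
12-month high-frequency blocks by their 6th month. Per-window uncertainty is
the SD of each coefficient over 500 case-resampling bootstrap replicates
(row resampling with replacement at the original n; rank-deficient resamples
are skipped and counted, more than 20% skips is an error); 95% intervals are
±1.96 bootstrap SD.

Tropical means are cos-latitude-weighted averages over vegetated land cells
between 24° N and 24° S (weighting can be switched off); missing cells are
ignored with weight renormalization. Temperature and radiation aggregate to
annual means, precipitation to annual totals (mm y⁻¹), so the coefficients
keep their natural units: γ in PgC y⁻¹ K⁻¹, τ in PgC y⁻¹ per mm y⁻¹, δ in
PgC y⁻¹ per W m⁻².

## Dryness stratification

A detrended water-availability series (precipitation by default; scPDSI,
SPEI, soil moisture or water storage enter as ready-made series) is divided
by its full-record population SD and classified as very wet (σ ≥ 1), wet
(0 ≤ σ < 1), dry (−1 ≤ σ < 0) or very dry (σ < −1). The boundaries are
implemented exactly as written, which makes the closure asymmetric: σ = 1 is
very wet but σ = −1 is dry. The high-frequency (n = 721) rows are pooled per
class and refitted with M1 — high frequency because four classes would leave
too few annual points per class. The same σ rule applied to pixel long-term
means against the *spatial* distribution yields dryness groups of pixels.

## Autocorrelation-robust inference

Adjacent 20-year windows share 19 years, so a window-γ trajectory is
smoothed noise: approximately a 20-term moving average of annual shocks,
with lag-1 correlation ≈ 0.95 and only ~3 effectively independent values per
42-window trajectory. All significance machinery in `robust.py` exists
because of this.

* **Theil–Sen / Mann–Kendall**: the Sen slope is the median pairwise slope;
  the MK test is the Kendall rank correlation against time (exact null at
  small n, tie-corrected normal approximation otherwise). Pre-whitening
  removes AR(1) dependence first. Three variants are exposed because the
  trade-off is real: `tfpw` (Yue–Pilon trend-free pre-whitening, the zyp
  default — full power, anti-conservative on trendless strongly
  autocorrelated series), `pw` (filter the raw series — near-nominal size,
  trend attenuated by 1 − r), and `ws` (iterative, bias-corrected r with
  amplitude restoration — best size control). `tfpw` is the package default
  because it is the variant the surrounding literature uses on window
  trajectories; users testing weak trends on strongly autocorrelated series
  should prefer `ws`. No pre-whitening variant can fix the moving-average
  dependence of overlapping windows: for "is this trajectory flat?"
  questions the annual-scale interaction probe below is the right tool.
* **Random-phase test**: correlation significance against surrogates of one
  series built by Fourier phase randomization (DC and Nyquist bins fixed),
  which preserves mean, variance and the full autocorrelation function.
  p = (1 + #{|r_surr| ≥ |r_obs|})/(reps + 1), two-sided, Spearman by default
  (Pearson by flag), 1000 surrogates by default. Randomizing only x gives a
  conditional test; symmetric randomization is available by flag.
* **Cochrane–Orcutt**: single-pass by default — OLS, residual lag-1 ρ,
  quasi-difference y and X by ρ (first row dropped), refit; iterated mode by
  flag; ρ can be forced. Raw and adjusted coefficients and Durbin–Watson
  indicators are both reported.
* **Durbin–Watson**: Σ(eᵢ−eᵢ₋₁)²/Σeᵢ², in [0, 4], 2 for white residuals.

## Factorial attribution

NBP's sign is inverted wherever it is compared with the growth rate
(uptake vs atmospheric accumulation). Scenario trajectories (SCE1: all
drivers vary; SCE2–SCE6: precipitation, radiation, CO₂, land use or N
deposition held at its 1960–2020 climatology) run through the identical
moving-window machinery; trajectory differences carry √(sd₁² + sd₂²).
Continental contributions are decomposed with lmg relative importance —
each predictor's sequential R² increment averaged over all orderings,
computed exactly through the subset (Shapley-weight) formulation, valid for
up to 6 predictors; shares sum to the full-model R². "Trends in γ" for the
flux-component regression are Theil–Sen slopes of γ over period halves.

Whether a scenario trajectory is "flat" is decided at the annual scale:
`moisture_modulation` regresses detrended −NBP on (ΔT, ΔP, ΔR, s·ΔT), where
s is the slow standardized water state; the s·ΔT coefficient is the
amplitude of the water modulation of γ, estimated with ~59 degrees of
freedom instead of the ~3 effective degrees of freedom of the window
trajectory. Trend tests applied directly to window trajectories reject far
too often under a flat truth (measured ~75% at the default noise level) and
are not used for this purpose.

## Synthetic data: what it emulates and what it does not

The generator makes the regression equations the literal data-generating
process. Monthly growth-rate anomalies γ(t)ΔT + τΔP + δΔR (+ θΔTΔP) + ε are
converted to ppm increments, cumulatively summed from 315 ppm at the lead
month, and a 3-ppm seasonal cycle is added (it cancels exactly in 12-month
aligned differences). Defaults, chosen once:

* γ(t): piecewise linear through (1960, 0.4), (1990, 6.4), (2020, 0.8)
  PgC y⁻¹ K⁻¹. A 20-year boxcar attenuates the underlying swing, so these
  knots are set such that the *window-mean* trajectory — the quantity the
  analysis estimates — rises from ≈2.4 to ≈5.4 and falls to ≈2.5, with
  half-period trends of ≈ ±0.15 PgC y⁻¹ K⁻¹ per year, the magnitude regime
  of the observed window estimates.
* τ = −0.005 PgC y⁻¹ per mm y⁻¹, δ = −0.05 PgC y⁻¹ per W m⁻², θ = 0 (wet
  and bright anomalies strengthen the sink, lowering the growth rate).
* Temperature anomalies: monthly AR(1), lag-1 0.5, SD 0.3 K (annual-mean SD
  ≈ 0.15 K). Precipitation anomalies: AR(1), SD 72 mm y⁻¹ as a rate, plus a
  slow sinusoidal component of amplitude 40 mm y⁻¹ and period 60 years with
  its dry trough at 1990 — the "bi-decadal" water state that both the γ(t)
  narrative and the flux generator's modulation key on. Radiation: AR(1),
  SD 1.5 W m⁻², correlation −0.4 with precipitation (cloudier wet spells).
* Regression noise ε: 0.25 PgC y⁻¹ annual-equivalent, about half the
  climate-driven signal SD.
* Optional Pinatubo-style perturbation: −1.5 PgC y⁻¹ in 1992–1993, for
  testing the exclusion logic.

Flux sets use a minimal response model per region (Africa 0.5, Asia-
Australia 0.3, South America 0.2 of the tropics): NPP gains from CO₂,
precipitation, radiation and N deposition and declines with land-use loss
and warming; Rh rises with temperature at a rate k_rh0 − gamma_moist·s(t)
(wet decades weaken the response — the water control of γ_NBP, with the
moisture modulation distributed 1.52/0.6/0.3 across continents so Africa
dominates); FIRE spikes by 0.8 PgC y⁻¹ only in months with precipitation
σ < −1; NBP = NPP − Rh − FIRE identically. Component noise is 0.2 PgC y⁻¹
annual-equivalent. Holding precipitation at climatology (SCE2) zeroes s(t)
and freezes γ_NBP at k_npp_t + k_rh0 = 3.2; the SCE1 − SCE2 γ difference
equals −gamma_moist·s̄(window), the known injected component.

All draws come from named child streams of a single seed; identical seeds
give byte-identical outputs, and scenario outputs do not depend on which
other scenarios are requested.

What the generator does *not* emulate: real seasonal-cycle amplitude growth,
volcanic aerosol physics, spatially heterogeneous teleconnections, observed
ENSO spectra (persistence is plain AR(1)), or process-model nonlinearity in
the flux responses. Passing tests therefore demonstrate that the estimators
recover the assumed statistical structure at realistic noise levels — not
that the structure is the right description of the real carbon cycle.

## Numerical choices and degenerate inputs

OLS is solved by `numpy.linalg.lstsq`; rank deficiency raises with the
offending columns named. Bootstrap replicates are solved in one batched
normal-equations call; resamples with condition number above 1e12 are
skipped. Station parsing treats values ≤ 0 as missing, re-orders shuffled
rows with a warning, and raises on duplicates and malformed rows with the
file and line named. Gridded input must be a contiguous monthly sequence;
0–360° longitudes are remapped to ±180°. Zero-variance series raise in
standardization, correlation and Durbin–Watson rather than returning NaN.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
analysis' native size (61 years, 732 months, 42 windows) and use 100 seeds
for trajectory recovery, 500 replicate pairs × 1000 surrogates for the
random-phase size check, and 50 seeds × 500 bootstrap replicates for the
scenario attribution — sizes at which the Monte-Carlo error of each reported
rate is a few percent.

## Known limitations

The high-frequency regression inherits strong serial dependence from
overlapping 12-month blocks; its bootstrap SDs understate uncertainty
there (the annual pipeline is the primary inference path). The lmg
decomposition is exact but limited to 6 predictors. The Cochrane–Orcutt
default is single-pass, matching the worked description it implements,
not the fully iterated estimator. σ-category boundaries follow the printed
rule, including its asymmetric closure at σ = ±1.
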