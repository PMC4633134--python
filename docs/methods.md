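# Methods

## Model chain and assumptions

The package treats a conditioner trial as a chain of four coupled
regressions, each with an explicit domain assumption:

1. **Thermal time** (`cottonlai.thermal`). Daily GDD is the FAO-capped
   average of the daily extremes minus the base temperature; both extremes
   are clamped into [T_base, T_upper] before averaging, so daily values are
   nonnegative and the cumulative series is monotone. The thresholds are
   crop- and site-specific and are *configuration*, not constants: the
   shipped defaults (10 °C base, 35 °C upper) are common cotton values, and
   both are overridable. Missing days are an error rather than being
   interpolated — no defensible gap rule exists without more weather data.

2. **Relative LAI growth** (`cottonlai.canopy`, `cottonlai.growth`). The
   central empirical fact the chain relies on is that conditioner type and
   rate change a treatment's *scale* (LAI_m) but not the *shape* of its
   LAI(GDD) trajectory. Normalizing each treatment by its own empirical
   maximum over the observed grid (never a fitted peak — that is what makes
   the peak grid point exactly 1) collapses all treatments onto one curve,
   summarized by the per-grid-point mean and sample (n−1) SD. Five
   single-peak forms describe that curve; for the exponential forms the
   amplitude is free rather than pinned to 1, because a discretely sampled
   trajectory peaks near, not at, the continuous curve's maximum.

3. **Dose response** (`cottonlai.dose`). LAI_m(I) and WUE(I) are concave
   quadratics in the application rate I, fitted by exact linear least
   squares; the vertex −c₁/(2c₂) is the optimum, reported at the reference
   precision (rates to 1 decimal, 3 significant figures for PAM; values to
   2 decimals). The control (rate 0) anchors every conditioner's curve. A
   convex fit has no interior optimum and is an error, not a warning.

4. **Biomass and yield** (`cottonlai.biomass`). The LAI–dry-matter link is
   Michaelis–Menten with asymptote P/Q; the default fit is ordinary least
   squares on the double-reciprocal line, exactly as this relation is
   conventionally estimated. The reciprocal transform is known to overweight
   small-M points; `method="nonlinear"` fits on the original scale and the
   report states which was used. Yield prediction assumes the harvest index
   is constant across treatments (observed scatter ≈ 0.0115 SD), so a
   single parameter — LAI_m — carries all treatment information. The yield
   predictor composes the HI factor with the inverted link; a folded
   closed-form display of the same model (coefficients 4.9159/0.7915 for
   HI = 0.5148) agrees with the composition to well under 0.5% over
   LAI_m ∈ [1, 3] and is treated as a display form only.

## Numerical choices

- **Fit statistics** (`cottonlai.metrics`). Re is implemented *with* a
  square root, 100·√(Σ(o−s)²/Σo²), although the relation is often displayed
  without one: only the rooted form lands on the same percent scale as the
  published relative errors for these fits (≈1% for the best curve, versus
  ≈0.01% unrooted). R² uses SS_tot about the observed mean and is an error
  on constant observations.
- **Optimizer.** The nonlinear forms are fitted by seeded multi-start
  bounded least squares (default 32 starts: one data-driven start — peak
  height/location, shape defaults, and a log-linearization for the modified
  logistic — plus uniform draws from the parameter boxes amplitude ∈
  [0.5, 1.5], peak a ∈ [observed GDD range], width b ∈ [10, 5000] (GDD
  forms) or [0.05, 5] (log-normal), exponent c ∈ [0.5, 10], and a
  documented box for the logistic's exponent coefficients). Fitting is
  deterministic per seed; correctness claims rest on fit quality, not on
  parameter equality with any particular optimizer's output. The cubic
  polynomial is linear in its coefficients and is solved exactly.
- **Tie-breaking.** Model comparison sorts stably by (RMSE, parameter
  count, input order), so ties preserve input order.
- **Units.** Canonical mass-area unit is kg/m²; t/ha tables are converted
  (×0.1) at the I/O boundary.
- **Parameter counts.** The Gaussian and log-normal forms have 3 free
  parameters, the modified logistic, modified Gaussian and cubic have 4;
  comparison tables report the actual count of free parameters.

## The virtual-trial generator

`cottonlai.synthetic` generates trials that are the *generative inverse* of
the analysis: true LAI_m from a per-conditioner quadratic, LAI trajectories
as LAI_m·RLAI_true(g)·(1+ε) with multiplicative Gaussian noise (CV-style,
matching the roughly scale-proportional spread of replicated canopy
measurements), dry matter from the inverted true link, and yield from a
jittered harvest index. Defaults are the reference trial's conditions: its
ten-treatment design and eight-point GDD grid, the modified-Gaussian shape
(a = 1772.98, b = 928.98, c = 4.49) with amplitude 1 — RLAI is by
definition normalized to peak 1, so the generator does not inherit the
reference fit's amplitude 0.9968, which is a fit artifact — the reference
link P = 10.1317, Q = 1.6312, HI = 0.5148 with its observed SD 0.0115 as
the HI jitter, and 2% CVs for LAI and biomass noise.

Two design choices matter for recovery testing. First, the three true
dose-response quadratics share a common intercept equal to the control's
LAI_m (2.27, the mean of the reference trial's separately fitted
intercepts): a single control observation must lie on *all three* curves,
or zero-noise recovery of the quadratic coefficients is impossible by
construction. The published curvatures and slopes — hence the published
optima — are kept. Second, the calibration/validation split governs the
growth-curve, link and HI stages, but the dose-response stage fits on every
treatment with an LAI_m: a conditioner contributes only two non-zero rates
to the calibration subset, which underdetermines a quadratic, and the
reference analysis itself fitted its dose curves on all rates plus the
control.

What passing recovery tests shows — and does not. At zero noise the
pipeline inverts the generator to ~5·10⁻⁵ relative (the residual is grid
sampling: the empirical maximum of an 8-point trajectory sits slightly
below the continuous peak). Under noise, errors grow stochastically with
the noise level. This demonstrates estimator consistency under the model's
own assumptions; it says nothing about spatial field heterogeneity,
correlated within-date measurement error, or weather-driven shape changes,
none of which are generated.

## Problem sizes

The shipped analyses operate at the reference trial's scale: 8 grid points
× 6–10 treatments for curve fitting, 4 points per dose-response quadratic,
6–10 points for the link fit. The noisy-recovery study uses 100 seeded
trials at 2% LAI noise; the noise-monotonicity check uses 8 seeds per
level, sizes chosen to keep the full suite near a minute while leaving the
Monte-Carlo conclusions stable across seeds.

## Known limitations

- The optimum is only meaningful inside the sampled rate range; the package
  logs no extrapolation warning beyond a note in reports.
- The double-reciprocal link fit inherits its classical bias under
  heteroscedastic noise; use the nonlinear option when small-M points are
  noisy.
- GDD accumulation has no photoperiod, chilling, or hourly interpolation;
  the base/upper thresholds must come from the user's agronomy.
- Reference summary tables carry printed rounding; recomputations from
  rounded columns can differ from printed summaries by up to one unit in
  the last printed digit (the package's tests account for exactly that).
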