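# Methods

This note records the models implemented in `bloomtrace`, the defaults and
why they hold, the design choices made where the design was genuinely open,
and what the synthetic data does and does not establish.

## Scene model and masking

A scene is a dated triplet of Rayleigh-corrected reflectance grids
(Red/NIR/SWIR) with a water mask and a cloud mask, at one of two processing
levels: `low_sensitivity` (top-of-atmosphere, L1C-like) and
`high_sensitivity` (bottom-of-atmosphere, L2A-like). Reflectance outside
[−0.05, 1.2] is treated as invalid (masked, never clipped): the lower bound
tolerates Rayleigh-correction overshoot over dark water, the upper bound
discards saturated or glint pixels. Invalid and cloudy pixels propagate as
absent values, never zeros, so they cannot deflate area statistics.

Coastal contamination (exposed sediment, adjacent land in mixed pixels) is
handled by eroding the water mask by a configurable Chebyshev radius
(default 2 px, ≈1 km on a 500 m grid). Erosion — excluding a near-coast
buffer — was chosen over its opposite reading (keeping only near-coast
water) because the purpose of the rule is to prevent land-driven false
positives; the buffer width is a config parameter so either geometry can be
explored.

## FAI and segmentation

FAI = NIR − [Red + (SWIR − Red)·(λ_NIR − λ_Red)/(λ_SWIR − λ_Red)], computed
in double precision with no clipping: negative FAI is the meaningful
clear-water baseline undershoot. The index is invariant to adding a
constant to all three bands (the property the baseline subtraction exists
for) and homogeneous of degree 1 under band scaling; both are enforced by
tests.

Segmentation uses a strict `>` cut. Shipped thresholds are 0.05 for the
modis-like sensor (λ = 645/859/1240 nm, 0.25 km² pixels) and 0.045 for the
s2-like sensor (B4/B8/B11, λ = 665/842/1610 nm, 10 m pixels); candidate
thresholds live on a 0.005 grid, values snapping to it by round-half-away-
from-zero. Extractions not exceeding `min_area` = 0.7 km² are zeroed — the
one numeric outlier rule used throughout.

### Automatic per-image thresholds

Optimal thresholds are historically picked by eye per image. The automated
stand-in here is a maximum-gradient criterion: among grid candidates that
split the valid area, choose the one whose segmentation boundary ring has
the largest mean spatial |∇FAI|. On a well-separated bimodal image every
cut between the modes yields the same boundary (the patch edge) and hence
the same score; near-ties within 1% of the best score therefore resolve to
the central candidate of the tied plateau — the cut least sensitive to
threshold perturbation, which is also what manual analysts converge to.
With an even tie count the smaller of the two central candidates is
returned (the more inclusive extraction). The scene-set optimum is the mode
of per-image thresholds, ties again toward the smaller value. Output
metadata labels these thresholds as automated proxies for manual judgment.

## STMW (Single Threshold Multi-stage Weakening)

One shared threshold (the high-sensitivity optimum, default 0.045) is
applied to both levels of a same-day scene pair. The day is *flagged* as a
bloom day iff the low-sensitivity area exceeds `min_area`; the reported
area is the high-sensitivity area (zeroed if itself ≤ `min_area`), or 0 on
unflagged days. Flagging uses area exceedance rather than max-pixel
exceedance so a single noisy pixel cannot flag a day; the `min_area` filter
is applied to both the flagging test and the reported area, the reading
that makes the two stages consistent. When the two levels are identical the
procedure reduces exactly to single-level segmentation.

## Area series and decomposition

Daily areas are smoothed with a centered moving average (default window 7,
odd required); at the edges the window shrinks symmetrically, preserving
length. A centered window was chosen to match the centered trend filter of
the decomposition. Monthly means include zero-area cloud-free days and
exclude unobserved days; months with no observations are absent and must be
filled (linear interpolation, filled entries flagged) before decomposition,
which requires a gap-free series of ≥ 24 months.

The classical additive decomposition (via `statsmodels.seasonal_decompose`)
takes trend = centered 2×12 moving average (undefined at 6 edge points per
side), seasonal factors = per-calendar-month means of the detrended series
re-centered to zero sum, irregular = remainder. The identity value = trend
+ seasonal + irregular holds exactly wherever the trend is defined; both
it and zero-sum are tested to 1e−9, with an independently hand-rolled
oracle cross-checking the library on a fixture.

Water-quality matching: because station sampling is sparse, a sampling date
is paired with the mean of *strictly positive* areas within ±`window_days`
(default 7, configurable in [5, 7]); zero-area days carry no bloom
intensity information for this purpose and windows with no positive
observation return an absent value.

## SARIMA (0,0,1)(0,1,1)₁₂ with drift

Model and recursion are given in the README. Numerical choices:

- **Estimation.** The series is explicitly differenced at lag 12 and the
  resulting intercept + MA(1) + seasonal-MA(1) model is estimated by exact
  Gaussian likelihood through the state-space innovations filter
  (statsmodels SARIMAX) under invertibility (|θ|, |Θ| < 1). An independent
  conditional-sum-of-squares estimator (pre-sample innovations at zero,
  first 13 periods excluded from the objective) serves as a test oracle;
  the two agree within one standard error on fixtures. If L-BFGS stops on a
  line-search failure with the gradient already negligible, a Nelder-Mead
  polish from the last iterate completes the fit.
- **Standard errors** come from the inverse observed information;
  t = estimate/SE and two-sided normal p-values are reported in a
  four-column table (parameter, estimate, std error, t, significance).
- **Simulation** draws Gaussian innovations (the minimal white-noise
  assumption), conditions pre-sample innovations to zero, and is
  deterministic per seed. With σ² = 0 the recursion produces an α₀-per-year
  staircase; fitting such a degenerate series raises a distinct
  degenerate-variance signal rather than crashing.
- **Forecasting** iterates the recursion with future innovations at their
  zero mean; beyond lag 13 the path is purely seasonal-plus-drift. Negative
  forecasts are reported as-is (the model is unconstrained); a
  clamp-at-zero flag exists for presentation only.

The reference parameter set used in worked examples and the acceptance
script is (α₀, θ, Θ) = (0.015, −0.217, 0.689) with σ² = 0.0025
(σ = 0.05 km²). σ is not part of the reference coefficient set; 0.05 km²
is the value consistent with the reference intercept standard error
(≈ 0.004 at ~264 effective observations) and with the km²-scale of monthly
bloom areas in a bay of this size. The expanded MA gives the lag-13
coefficient θΘ = −0.1495 ≈ −0.150.

Recovery study sizes: 200 replicates of length 276 (23 years, matching a
22-year record plus forecast year) — enough for the replicate-mean
estimates to settle well inside ±0.05 (MA coefficients) and ±0.01 (drift)
while the full study completes in well under a minute.

## Association statistics

Pearson r² and Spearman ρ (average ranks for ties) on complete pairs, with
zero-variance inputs signalled as undefined rather than returned as NaN.
OLS reports use an intercept, residual-variance SEs and t-distribution
p-values; rank-deficient designs raise an error naming the dependent
columns, and exact fits are flagged degenerate instead of reporting zero
SEs as sound. Both a single multivariate fit (default) and per-factor fits
are available, since sparse station data can make either report shape the
appropriate one.

## Synthetic data: what it emulates and what it does not

**Scenes.** 256×256 grids of 10 m pixels: Gaussian background reflectance
(σ = 0.002 per band, background FAI ≈ −0.006), a land strip defining the
coast, disk-shaped bloom patches (NIR amplitude 0.08 → FAI ≈ 0.074 at the
low level, ~1.13 km²) and near-coast sediment patches (amplitude 0.03 →
FAI ≈ 0.024 low / 0.054 high, ~0.79 km²). The L2A-vs-L1C sensitivity
difference is modelled as a constant additive NIR offset δ = 0.03 applied
to the high level — the simplest mechanism producing the observed nesting
(every low-level extraction ⊆ high-level extraction) — with the sediment
amplitude chosen to straddle the shared 0.045 threshold across levels, so
sediment is extracted only at the high level. Margins to the threshold are
≥ 4 noise SDs on every class, which is why truth-mask recovery and the
≥ 50% false-positive suppression assertions hold by construction.
Multiplicative gain differences, spatially correlated noise, adjacency
effects, sub-pixel mixing and realistic coastline geometry are *not*
modelled: passing tests show the algorithms implement their definitions,
not that real L1C/L2A imagery behaves this simply.

**Monthly series.** 22 years at baseline 0.30 km², flat until year 17 then
rising at 0.05 km²/yr (a stable-then-increasing record), the default
zero-sum seasonal vector (September maximum +0.40, March minimum −0.30),
and seasonal-MA noise at the reference parameters, truncated at zero.
Truncation makes the generator realistic (areas are non-negative) but
slightly non-Gaussian; the SARIMA recovery study therefore simulates from
the untruncated recursion.

**Drivers.** Linear couplings with configurable noise: SST positive, wind
speed and pressure negative, dissolved oxygen negative, petroleum positive.
These encode sign structure only; they are not a physical forcing model.

## Known limitations

- No atmospheric correction: inputs must already be Rayleigh-corrected.
- No reprojection or tiling; grids are used as given.
- The per-image threshold criterion is an automated proxy for manual
  selection; only its behaviour on bimodal fixtures is validated.
- The decomposition requires gap-filled months; long gaps interpolated
  linearly will damp the seasonal factors.
- The SARIMA order is fixed; no order search or diagnostics beyond the fit
  report.
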