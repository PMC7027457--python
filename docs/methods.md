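# Methods

This note documents the models implemented in `microfutures`, their
assumptions, the parameters that matter, and the numerical choices made
where the design was genuinely open. Everything quantitative stated here is
computed by the test suite or `scripts/acceptance.py`; nothing is quoted
from external data.

## Scope and data model

The package targets small coastal temperate landscapes (the defaults assume
~50° N, maritime climate, ~12 km coarse climate cells, 1–100 m output
grids). Rasters are square-celled, north-up, in a projected metric CRS;
geographic lat/lon grids are rejected because all terrain operators (slope,
horizon, flow routing) assume metric cell sizes. Row 0 is the northernmost
row and values refer to cell centres. On disk, 2-D layers are ESRI ASCII
grids (plain text, 9 significant digits — enough to round-trip float32 bit
exactly) with a `.prj` sidecar carrying the CRS identifier; reading a grid
without a sidecar is an error rather than a silent default. Stacks of
(time, y, x) fields are NetCDF3 with a CF time axis; station and logger
series are CSV with ISO-8601 timestamps.

## Bias adjustment (quantile mapping)

Model runs and observations over a common historic window are compared per
variable. Both samples are ranked and `n_points = 1200` paired order
statistics are drawn at equal probability intervals, jittered uniformly
within each interval by the operation's own RNG. The monotone smooth through
the pairs is implemented as isotonic regression (pool-adjacent-violators) on
the paired quantiles followed by monotone piecewise-cubic (PCHIP)
interpolation; a penalized monotone spline would serve equally, but the
isotonic + PCHIP composition is monotone *by construction*, cannot fold at
the extremes, and needs no smoothing parameter. Outside the calibration
range the transform continues linearly with slopes estimated from the
terminal 5% of knots, so extreme future values map through a controlled
extrapolation and the order of inputs is always preserved.

Diagnostics stored with the fit: two-sample Kolmogorov–Smirnov distance
before and after adjustment. On 10⁵-sample fixtures with known shift/scale
biases the adjusted KS distance is ≲ 10⁻³ and the interior transform error
is far below 5% of the sample SD (see `test_acceptance.py`).

The 1,200-knot default is meant for hourly-scale samples; the pipeline demo,
which adjusts daily series, caps the knot count at the sample size.

## Daily → hourly disaggregation

- **Temperature**: a dimensionless diurnal shape rises as a half-sine from a
  minimum at sunrise to a maximum at sunrise + 0.55 × daylength (the lag is
  configurable), falls through the afternoon and decays exponentially
  overnight. The 24 sampled values are affinely rescaled so the hourly
  minimum and maximum equal t_min and t_max *exactly* — the daily extremes
  are treated as hard data, the shape only as an interpolant.
- **Shortwave**: the daily total (MJ m⁻² day⁻¹) is distributed over hours
  proportionally to the clear-sky flux from solar geometry, hence zero at
  night and conserving the total to machine precision.
- **Humidity and pressure**: linear interpolation between noon-anchored
  daily values of the neighbouring days.
- **Wind speed**: constant within the day; direction drawn per day from a
  configurable climatology (default south-westerly maritime).

Solar geometry uses the NOAA low-accuracy algorithm (declination and
equation-of-time Fourier expansions); verified against reference geometry to
well under 0.5°.

## Mesoclimate

**Coastal exposure**: for each cell and each of `n_dir = 8` from-directions,
a ray of sample points at one-cell steps is cast to a 10 km default radius;
exposure is the inverse-distance-weighted (w ∝ 1/d) fraction of sea samples.
Rays continue the edge value beyond the domain. The all-direction mean is
the second covariate. Both radius and direction count are configurable; the
upwind value uses the single sector nearest the wind direction (a documented
simplification rather than sector interpolation).

**Spline surface**: the land–sea differential for one hour is regressed on
(elevation, upwind exposure, mean exposure) with a thin-plate spline
(`scipy` RBF with a degree-1 polynomial tail). Covariates are standardised;
constant or duplicated covariate columns are dropped automatically to keep
the polynomial block nonsingular. The smoothing parameter is selected by
leave-one-out cross-validation over a log-spaced grid — at the sample sizes
involved (tens of coarse cells) this is an exact stand-in for generalized
cross-validation. Because of the polynomial tail, responses affine in the
covariates are reproduced exactly at any smoothing; fixture recovery of an
affine elevation/exposure response reaches R² = 1.0 on the fine grid.

**Precipitation**: per calendar month, thin-plate splines of monthly total
and rain-day count on elevation are fitted at coarse scale (ordinary least
squares on elevation when fewer than 10 cells are available) and predicted
at fine scale. Each fine cell takes the daily pattern of its nearest coarse
cell rescaled to the predicted monthly total; wet days are then toggled —
smallest wet days dried into the wettest day, or dry days topped up from
it — until the wet-day count matches, conserving the monthly total at every
step and never producing negative values.

## Microclimate temperature anomaly

The near-surface anomaly is ΔT = c₀ + c_base·R_net/(1 + c_wind·u_z).
The hyperbolic wind term is the simplest one-parameter form with the right
asymptote (ΔT → c₀ as u → ∞, full turbulent mixing); alternative decay
forms can be swapped behind the same interface. Latent and soil heat fluxes
are not modelled separately — they are assumed small and proportional to net
radiation, so they fold into c_base.

Net radiation combines: Erbs clearness-index split of global shortwave into
direct and diffuse; direct beam projected on slope/aspect and removed when
the sun is below the local horizon angle; diffuse scaled by sky-view
(mean cos² horizon angle over 24 directions); canopy transmission
(1 − cover); albedo default 0.23 (grass reference surface); and FAO-56 net
longwave (vapour-pressure clear-sky emissivity, cloud correction from the
received/clear-sky shortwave ratio, carried overnight from the previous
afternoon), scaled by sky-view. Wind is height-adjusted by the logarithmic
profile (z₀ = 0.01 m for grass) and damped by the Ryan topographic shelter
coefficient, implemented as S = 1 − 0.00882·θ_up (θ_up the upwind terrain
angle in degrees, floored at 0, clipped to [0, 1]) per 45° wind sector.

Calibration is trust-region nonlinear least squares from five fixed starting
points (the attenuation rate enters as |c_wind|, keeping the search
unconstrained). Calibration/validation data are split by site *and* by
contiguous time block, so the validation half shares neither location nor
period with the calibration half. Standard errors come from the Jacobian at
the optimum. Under the synthetic conditions (8 loggers, one year hourly)
noise-free recovery is exact to ≪ 1%; with 0.5 °C Gaussian sensor noise the
radiative coupling gradient recovers to a few percent and the held-out RMSE
reproduces the injected noise (ratio ≈ 1.0). The wind-attenuation rate is
the least identifiable parameter and its recovery error can reach ~10% at
unfavourable seeds — a property of the estimation problem, not a defect.

## Soil moisture

Two layers: d₁ = 0.05 m (bare-soil evaporation source) and d₂ = 0.95 m
(storage); the deep default deliberately buffers the uniform-soil
assumption. Van Genuchten parameters default to a loam
(θ_r = 0.078, θ_s = 0.43, α = 3.6 m⁻¹, n = 1.56, K_sat = 0.2496 m day⁻¹).
Daily order of operations per cell:

1. Curve-number runoff: S = 25400/CN − 254 mm, I_a = 0.2 S,
   Q = (P − I_a)²/(P + 0.8 S); the average-condition CN (default 75) is
   mapped to wet/dry equivalents by the standard AMC I/III formulas with
   5-day antecedent-precipitation thresholds 12.7/27.9 mm.
2. Infiltration of throughfall plus yesterday's ponded water into layer 1 up
   to saturation; excess ponds in a surface store.
3. Evapotranspiration: daily FAO-56 Penman–Monteith demand (hourly form,
   G = 0.1 R_n day / 0.5 R_n night, summed over 24 h), split as
   bare-soil fraction (default 0.2) from layer 1 only and vegetation
   transpiration half from each layer, each stream scaled linearly once
   content falls below the mid-point of the available range and capped at
   water above θ_r.
4. Inter-layer exchange: flux = D(θ̄)·(θ₁ − θ₂)/Δz + K(θ̄) (gravity term
   downward), with D = K·d|ψ|/dθ from the analytic retention-curve
   derivative, integrated in 24 explicit sub-steps with flux limiting —
   daily explicit steps are unstable at high diffusivity, and the limiter
   guarantees both layers stay inside [θ_r, θ_s].
5. Deep drainage K(θ₂) leaves layer 2 within the same sub-steps.
6. TWI redistribution: within each basin, each layer's water is reallocated
   so content is linear in TWI quantile while conserving the basin total
   exactly (clipped surplus is spread over unclipped cells, with a final
   exact correction on the cell with most head-room).
7. Overflow: surface water beyond a per-cell capacity (default 10 mm) spills
   to the downstream basin's pour-point cell; basins are processed from the
   highest pour-point elevation downwards; basins with no downstream export
   out of the domain.

Basins are delineated by D8 steepest descent with a deterministic micro-tilt
(≤ 10⁻⁹ × cell) to break perfect ties, flats resolved by breadth-first
drainage toward resolved neighbours; each interior pit's catchment is a
basin, all cells draining off the land area form the outlet basin. A basin's
pour point is its lowest boundary saddle, its downstream neighbour the basin
across that saddle; two basins sharing an equal saddle would point at each
other, so the cycle is cut at the basin with the lower floor (the pair's
true sink). TWI = ln(a / tan β) with D8 accumulation and slope floored at
0.001 rad.

Since no calibration exists anywhere in this component, correctness rests on
the water budget: precipitation = Δstorage + runoff + actual ET + drainage +
export, audited every day. Over a three-year fixture run the worst daily
closure error is ~4 × 10⁻¹¹ mm (tolerance 10⁻⁶ mm).

The 0–10 cm product is the thickness-weighted mean of the two layers over
the top 0.10 m.

## Bioclimate variables and novelty

Monthly building blocks come from hourly temperature (monthly mean, monthly
mean daily maximum/minimum) and daily precipitation. "Quarters" are all 12
contiguous 3-month windows, wrapping across the year end, with the extreme
window chosen per variable (Worldclim convention). BIO4 is the population SD
of monthly means × 100; BIO5/BIO6 are the hottest/coldest month's mean daily
extremes; BIO3 = BIO2/BIO7 × 100. BIO15 is the coefficient of variation of
monthly *mean daily* precipitation (×100): normalising by month length stops
the 28–31-day calendar from registering as seasonality, so a constant
drizzle scores exactly 0.

The growing season is the set of days whose centred 5-day means satisfy
precip > 0.5 × PET and 5 ≤ T ≤ 35 °C (windows truncated at series edges).
Physiological variables: frost hours (T < 0 °C), frost-free season (longest
run of days with no sub-zero hour), hours > 25 °C, waterlogged spell
(moisture ≥ θ_s − 0.01), drought spell (moisture ≤ wilting point, taken from
the inverse retention curve at −150 m ≈ −1500 kPa), growing degree-hours
over a 5 °C base (consistent with the growing-season lower bound) divided by
1,000.

Decadal trends are OLS slopes on annual values × 10. Novelty bins the
historic sample and the pooled future runs on one common grid spanning their
union (Freedman–Diaconis width on the pooled sample, clamped to 4–200 bins,
overridable); novelty = 1 − Σ min(p_hist, p_fut). It is symmetric,
invariant under joint affine rescaling, 0 for identical samples and 1 for
disjoint supports; two uniforms overlapping on half their width score 0.5.

## Synthetic fixtures: what they do and do not show

The generators reproduce the *structure* the models need: a coastline with
directional exposure gradients, enclosed depressions for routing, seasonal +
AR(1) temperature with elevation-lapse coherence between coarse cells
(lapse −0.006 °C m⁻¹), clear-sky-bounded shortwave, first-order Markov
precipitation occurrence (p_wet|wet = 0.6, p_wet|dry = 0.25) with gamma
amounts (shape 0.8, mean 6 mm), and loggers generated through the forward
anomaly model with known coefficients (defaults c_base = 0.01 °C/(W m⁻²),
c_wind = 1.0 s m⁻¹, c₀ = 0) plus Gaussian sensor noise. Each generator owns
an RNG stream keyed by (master seed, generator name), so outputs are
bit-reproducible and adding a generator never perturbs another.

They do **not** emulate the full spatio-temporal covariance of a regional
climate model, weather-type persistence beyond AR(1)/Markov order one,
inter-variable physical consistency beyond simple couplings (cloud–rain,
cloud–diurnal-range), or observational error structure beyond i.i.d.
Gaussian noise. Passing tests therefore demonstrate correctness of the
implementation and identifiability under known ground truth — not skill on
real landscapes.

Default problem sizes (32 × 32 fine grid, 4 × 4 coarse grid, two historic
plus two future years for the end-to-end run; one year of hourly data for
calibration studies; three years for the soil audit) were chosen as the
smallest landscapes that exercise every code path — coastline, multiple
basins, seasonal cycles — while keeping a full run interactive.

## Known limitations

- Hourly mesoclimate splines are refit per hour; the per-(hour, wind-sector)
  coefficient cache required for long landscape runs is not yet implemented.
- Upwind exposure and shelter use the nearest direction sector rather than
  interpolating between sectors.
- Canopy is time-invariant; no below-canopy vertical profiles, no 3-D
  radiative transfer.
- No channel routing or groundwater; surface overflow moves in one daily
  hop between basins.
- Reprojection between CRSs is out of scope — inputs must share one
  projected CRS.
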