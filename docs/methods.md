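# Methods

This note documents the models behind `algaecast`, their assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Problem setting

A grower must choose, one month ahead, which microalgal strain to inoculate
and at what depth to operate a well-mixed raceway pond. The decision
variable is a *strategy* — a (strain, depth) pair from a configured set
(default depths 15, 20, 25, 30 cm; two strains) — and the objective is
areal biomass production (g/m²/day) over the coming calendar month.
Forecast ensembles of hourly weather drive a pond-temperature model and a
growth model for every member × strategy; the strategy with the highest
ensemble-mean production is selected. Decision quality is scored against
"truth" runs: the same simulator driven by observed (here: synthetic-
archive) weather, so truth and forecast differ only in forcing.

## Meteorological conventions

Hourly series carry air temperature and dewpoint (°C), wind speed (m/s),
pressure (kPa), shortwave radiation (W/m²) and precipitation (mm/h) on a
strictly contiguous 1-hour local-standard-time index (no DST, so solar
geometry uses a fixed offset). Readers convert declared foreign units at
ingest; everything downstream assumes the package units. Days with fewer
than 24 records are dropped (with a logged warning) by daily aggregation
rather than imputed. PAR is `shortwave × 0.45 × 4.57` µmol photons/m²/s;
both constants are exposed because the broadband-to-PAR conversion is a
convention, not a measurement.

## Daily-to-hourly disaggregation

Seasonal forecast products issue daily members (Tmax, Tmin, precipitation,
humidity, wind, pressure); the simulators need hourly forcing.

* **Temperature**: cubic Hermite segments with zero slope at each anchor
  connect the previous day's maximum (15:00), today's minimum (sunrise,
  rounded to the hour), today's maximum (15:00) and the next day's minimum.
  The curve attains Tmax and Tmin exactly, is continuous across midnight,
  rises monotonically from sunrise to mid-afternoon, and is clipped to
  [Tmin, Tmax] so a hot previous evening cannot leak above today's
  maximum. Anchor times (`hour_of_tmax`, `hour_of_tmin`) are config.
* **Shortwave**: Bristow–Campbell transmittance
  `τ = τ_max (1 − exp(−B ΔT^C))` with defaults `τ_max = 0.75`,
  `B = 0.036 °C⁻ᶜ`, `C = 2.4`, multiplied by a wet-day factor (default
  0.75) whenever daily precipitation is positive — precipitation is the
  cloudiness proxy. Hourly flux is τ × top-of-atmosphere flux from
  standard solar geometry (Cooper declination, solar constant 1361 W/m²;
  |latitude| ≤ 66.5° — no polar day/night handling).
* **Humidity**: dewpoint is held at Tmin (air is assumed to saturate around
  dawn) unless the daily record carries specific humidity, in which case
  dewpoint comes from inverting the Magnus saturation curve at the day's
  pressure. Hourly dewpoint is clamped to the concurrent air temperature.
* Wind and pressure persist within each day; daily precipitation is spread
  uniformly over 24 hours.

Re-aggregating the output recovers the daily Tmax/Tmin exactly and precip
totals to float precision — the property the tests enforce. The scheme is
deterministic and is *not* a line-by-line port of any particular MTCLIM
release; coefficients are config, not claims.

## Ensembles

*Climatology (ESP)*: one member per archive year strictly before the
target year, each a verbatim slice of that year's target month re-stamped
onto the target dates. February length mismatches are resolved by reusing
Feb 28 for a missing Feb 29 and dropping Feb 29 for a non-leap target, so
all members have equal length. A gap-free archive starting in 1979 yields
41 members for 2020 targets and 45 for 2024 targets.

*Model*: daily members are disaggregated (members may carry one buffer day
each side for diurnal continuity, then are trimmed to the month) and
pooled with member count preserved; ensembles from several sources combine
by simple concatenation into a multi-model ensemble with source-prefixed
member ids. No bias correction or member weighting is applied.

## Pond thermal model

The pond is a single fully mixed column of fixed depth (operational depth
is a strategy variable, held constant within the month; evaporative depth
loss is ignored). The surface balance per unit area is

```
net = SW(1−α) + ε_w ε_sky σ T_a⁴ − ε_w σ T_w⁴ − f(u)(e_s(T_w) − e_a)
      − f(u) γ (T_w − T_a) + κ (T_g − T_w)
```

with water albedo α = 0.06, emissivity ε_w = 0.97, Brutsaert clear-sky
emissivity `ε_sky = 1.24 (e_a[hPa]/T_a[K])^{1/7}` (an explicit
`sky_emissivity` override exists for idealized configurations where the
isothermal state should be an exact equilibrium), a linear evaporative
wind function `f(u) = 30 + 20 u` W/m²/kPa, Bowen coefficient γ = 0.061
kPa/°C, and ground conduction κ = 0.5 W/m²/°C toward T_g = 15 °C. These
are generic pond-model magnitudes, **not** a calibration to any site;
every coefficient is a `ThermalParams` field. Integration is explicit
Euler at 1-hour forcing resolution with automatic sub-stepping whenever a
sub-step would change temperature by more than 0.5 °C; monthly runs start
from 5 °C (a deliberate cold start that removes initial-condition memory
from the comparison), and temperatures are clipped to a physical window
(−5…45 °C) with a warning — midsummer afternoons in shallow ponds can
touch the ceiling for a few hours. Net flux is strictly decreasing in
water temperature, so the constant-forcing equilibrium is unique; the
tests locate it independently by bisection.

## Growth model

A strain is an empirical surface: net specific growth rate (1/day) on a
(temperature × PAR) grid, bilinearly interpolated, plus a dark respiration
rate. The zero-light column must equal −respiration (enforced at load).
Light outside the grid clamps to the edge; temperature outside the
declared valid range either clamps to the boundary or switches to a
configured die-off rate, per strain. This deliberately avoids inventing
kinetics where the underlying parameterization is tabulated laboratory
data. Assumptions inherited from that setting: nutrient-replete, optimal
pH, well-mixed, no contamination, no salinity effect (salinity is
metadata).

Light at depth: Beer–Lambert with `k = k_w + k_c C` (defaults 0.2 /m and
50 /m per g/L) and column average `Ī = I₀(1 − e^{−kd})/(kd)`. Some
depth–light coupling is required for depth to be a meaningful decision;
the biomass term makes self-shading bite as the culture densifies.

Hourly update: `C ← C e^{μ Δt/24}`; at PAR = 0 the rate is −respiration.
Harvest is checked hourly: at ≥ 0.5 g/L the pond is instantly diluted to
0.1 g/L and `(C − 0.1) × d × 10` g/m² is credited. Monthly production is
(total harvested + final standing mass)/days; the inoculum (0.05 g/L)
counts as standing mass unless `subtract_inoculum` is set — the accounting
sentence is ambiguous in the source material, so both are available. The
mass ledger (inoculum + net biological increment = harvested + standing)
closes to ~1e-15 relative and is asserted at 1e-6.

## Decision rule

Strategies are the Cartesian product of strains and depths in
deterministic order (strain order × ascending depth). Ranking uses the
ensemble mean only; spread is reported but unused (risk-adjusted ranking
would be an extension, not the default). Exact ties break to the
shallower depth, then registry order — shallower is cheaper to operate —
and are flagged. The State-of-Technology baseline is a fixed rule: 20 cm
year-round, cold strain November–March, warm strain otherwise.

## Verification

* **CRPS** uses the closed form `mean|Xᵢ − x| − ½ mean|Xᵢ − Xⱼ|`,
  equivalent to integrating the squared difference between the empirical
  CDF and the observation step function; the tests verify the equivalence
  against exact piecewise integration to 1e-6. Daily CRPS aggregates to
  calendar-month means across years; the daily temperature statistic
  (mean/max/min) is a caller choice.
* **Accuracy**: confusion matrix of selected vs optimal strategies; total
  accuracy is the diagonal fraction; strain-only accuracy ignores depth
  and is structurally ≥ total.
* **ANOVA**: classical balanced two-way sums of squares on a
  (strain × depth × year) array, reported as ratios of the total sum of
  squares (they sum to 1); requires ≥ 2 replicate years per cell,
  non-constant data, and a balanced design — unbalanced input is an
  error, not silently reweighted. Computed per calendar month across
  years.
* **Production comparisons** report per-month percent differences and a
  headline difference computed from the two period-average productions
  (not the average of monthly percentages); percent values are carried
  unrounded internally.

## Synthetic study conditions

The generator emulates a hot semi-arid site: latitude 33.4°, annual-mean
air temperature 20 °C, seasonal semi-amplitude 9 °C (peak mid-July),
diurnal range 10 °C, AR(1) interannual anomalies (sd 0.9 °C, ρ = 0.6) and
AR(1) synoptic anomalies (sd 1.8 °C, ρ = 0.7), seasonal wet-day
probabilities (0.15/0.06/0.12/0.08 for DJF/MAM/JJA/SON) with exponential
wet-day amounts (mean 6 mm), and hourly structure produced by the same
disaggregation scheme used for forecast members, so archive and forecasts
share diurnal construction. Daily weather is seeded per (spec seed, year),
so any sub-period regenerates identically regardless of the span
requested. Forecast members equal the truth dailies plus noise scaled by
(1 − skill): member bias sd 2.5 °C, daily noise sd 2.0 °C, multiplicative
range/precip noise, and precipitation occurrence flips with probability
0.3 at zero skill — magnitudes chosen to be comparable to seasonal-
forecast errors so that the skill dial spans "decisions always right" to
"decisions degraded but not random". At skill = 1 members reproduce the
truth bit-for-bit, which makes perfect-skill decision accuracy exactly
100% by construction.

Archetype strains are smooth surfaces
`μ(T, I) = μ_max e^{−((T−T_opt)/b)²} · I/(I + K_s) − r_dark` (optional
photoinhibition divisor above an onset intensity): warm (T_opt 30 °C,
b 6 °C, μ_max 2.8/day, K_s 250 µmol/m²/s, r 0.18/day) and cold (T_opt
18 °C, b 8 °C, μ_max 2.0/day, K_s 200, r 0.12). μ_max is the asymptotic
light-saturated gross rate, so the realized peak sits below it by the
saturation discount and respiration. The respiration and half-saturation
magnitudes matter structurally: they are what make depth a genuine
trade-off (deep ponds carry more respiring biomass per unit of captured
light and run cooler; shallow ponds cycle faster but overheat in summer),
producing month-dependent optima and hard transition months instead of a
degenerate "deepest always wins" problem.

What the generator does **not** emulate: monsoon dynamics, real NMME
biases, station-merging artifacts, humidity regimes decoupled from Tmin,
or any statistical match to a specific location. Passing tests therefore
demonstrate the machinery and its structural behavior (perfect-skill
decisions are perfect; accuracy does not increase as skill is removed;
strain choice is more robust than depth choice), not predictive skill on
real data.

## Numerical choices and degenerate inputs

Bilinear interpolation clamps rather than extrapolates. The transparent
limit of depth-averaged light (`kd → 0`) returns the surface value. The
pond integrator aborts with a diagnostic if stability would require more
than 256 sub-steps per hour. Zero temperature range yields zero estimated
solar flux (the degenerate limit of the transmittance form). Empty
ensembles, misaligned series, non-contiguous indices, duplicate
timestamps, unbalanced ANOVA designs, constant-data variance partitions
and nonpositive baselines are errors, not warnings. Percent differences
are displayed to one decimal but computed unrounded.

## Problem sizes used in the shipped runs

The test suite and acceptance script use: a 45-year synthetic archive for
member-count bookkeeping; a 2-year archive and 12 validation months for
the decision harness (two strains × four depths, 6-member forecast
ensembles, 20 seeds for the skill-monotonicity check); 200 random
ensembles (n ≤ 6) for the CRPS oracle; and (2 × 4 × 8) arrays for the
ANOVA oracle. These sizes were chosen as the smallest that exercise every
code path and stabilize the stochastic averages.

## Known limitations

No 2-D hydrodynamics or stratification (the pond is one well-mixed box);
no pH/CO₂/nutrient dynamics; no contamination or crashes; depth fixed
within a month (no evaporation/rain depth dynamics); thermal coefficients
are generic, not calibrated; the growth surfaces shipped are synthetic
archetypes, not measured strains — user-supplied grids are the intended
path for real work; climatology ensembles assume a stationary climate.
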