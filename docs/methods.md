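# Methods

This note documents the models and procedures implemented in `forestharm`,
the assumptions behind them, the tunable parameters and their defaults, what
the synthetic-data generators emulate, and the numerical choices made where
the design was genuinely open.

## Discrete vegetation states

A stand-year is reduced to a categorical state over three axes.

*Composition.* Basal-area shares are fractions of total stand basal area in
[0, 1] summing to ≤ 1 (an implicit remainder of further minor species is
allowed). A species is **dominant** if its share strictly exceeds the
dominance threshold (default 0.66) and **admixed** at or above the admixture
threshold (default 0.20). Because shares sum to ≤ 1 at most one species can
exceed 0.66, so the dominant is unique; this is asserted, never assumed.
Species codes take the first two letters of genus and epithet after
whitespace trimming and case folding (dominant upper-case, admixed
lower-case); names whose genus or epithet is shorter than two letters (e.g.
hybrid notations like "Quercus x") are rejected. The state stores codes, not
full names, so encoding and decoding are exact inverses.

Conventions the encoding grammar needs but that worked examples alone do not
fix:

* **Admixed ordering** — descending share, ties broken alphabetically by
  code. A canonical string requires a total order.
* **No dominant** — the composition block is the concatenation of lower-case
  admixed codes.
* **No species ≥ 20 %** — the literal token `mixd`. A total encoding needs a
  non-empty block; `mixd` cannot collide with a real code in practice, and
  the decoder treats a lone `mixd` block as the empty stand.

*Function.* LAI class 1 for LAI < 2, class 2 for 2 ≤ LAI ≤ 4, class 3 for
LAI > 4; both boundary values fall in class 2.

*Structure.* Dominant height is grouped into 2-m bins treated as half-open
[lower, upper): 20.0 m falls in (20, 22). Floor arithmetic makes the
assignment deterministic at boundaries.

## Dominant-height harmonization

Contributing models report any non-empty subset of minimum, mean and maximum
canopy height. Harmonization to dominant stand height dispatches as follows:

1. mean missing, min and max present → mean = (min + max)/2;
2. max missing, mean present → max predicted by the **max-height model**
   (linear mixed model `max ~ mean`, per-species random intercept and slope,
   REML), floored at the mean to preserve the physical ordering — a
   constraint the statistical model does not know about;
3. with mean and max in hand, dominant height is
   * `factor(species) × max` when the stand's dominant species has an entry
     in the allometric-factor table (shipped for Scots pine, silver fir,
     European larch, Norway spruce, European beech and pedunculate oak with
     a documented placeholder of 0.95 each — the published per-species
     factors are not reproduced here and can be dropped in via
     configuration), or
   * the **dominant-height model** (linear mixed model
     `dominant ~ mean + max` with per-species random slopes on both
     predictors and no random intercept, REML) for all other species;
4. the result is clamped to [0.8 × max, max] for robustness to outliers.

Species absent from the calibration data receive the fixed-effects (
population-level) prediction. The clamp is applied before height binning.

**Degenerate calibration data.** When the calibration table is exactly
linear per species (zero residuals), the REML profile is degenerate: the
residual variance estimate collapses to zero and the optimizer cannot move.
The fit functions detect this case (max per-species least-squares residual
below 1e-9 relative) and return the per-species ordinary-least-squares
solution directly, with fixed effects defined as the mean of the per-species
coefficients and random effects as the deviations. On noisy data the
standard `statsmodels` MixedLM machinery is used; variance-explained
diagnostics follow the marginal/conditional decomposition (fixed-effect
variance vs. fixed + random over total).

Note an identifiability limit: if maximum height is an exact linear function
of mean height, the two predictors of the dominant-height model are
collinear and its coefficients are not identifiable in principle. Real
stands (and the generator, through its stand-level spread parameter) break
this collinearity.

## Climate matching

The catalogue holds daily trajectories (tas °C, prec mm, rad W/m², vpd kPa;
365 values per year, no leap days) per scenario × 0.11° grid cell, for
historical conditions and three RCPs, each driven by three GCMs — 12
scenarios.

*Trajectory selection.* Candidates are restricted by the simulation's
trajectory family — baseline → historical members only; an RCP hint → that
RCP's three members; a GCM hint narrows further; SRES or unhinted future
runs are compared against all nine RCP members — and evaluated at the grid
cell nearest the simulation's location (great-circle distance on cell
centers). Warming and precipitation trends are OLS slopes of the annual
series; the precipitation slope is divided by the series mean to make it
relative. The selection index is ΔT + 0.1·ΔP with **ΔT in °C per century
and ΔP in percent precipitation change per century**, absolute values taken.
The units are a design decision: they make the 0.1 weight mean "a 10 %
precipitation change trades against 1 °C", consistent with the year-level
index where the multiplicative precipitation difference is naturally a
percentage. Ties break to the lexicographically smaller scenario id.

*Level adjustment.* δ = (simulation mean MAT − trajectory mean MAT) is added
to every daily temperature; f = (simulation mean ANP / trajectory mean ANP)
multiplies every daily precipitation; radiation and VPD are untouched. Means
are computed over the simulation period intersected with the trajectory
period (full trajectory period when simulation years are indices rather
than calendar years). After adjustment the trajectory reproduces the
simulation's mean MAT and ANP to floating-point accuracy.

*Year matching.* For each simulation year the index
|ΔT| + 0.1·|100·(P_sim/P_scen − 1)| is computed against every scenario year;
one of the three smallest (ties resolved toward earlier years via a stable
sort) is sampled uniformly with replacement. The 3-best pool is recomputed
per simulation year. Sampling uses one pipeline-level seed with
per-simulation substreams derived from a CRC32 hash of the simulation id,
so results do not depend on processing order.

## Soil vectors and plant-available nitrogen

Plant-available nitrogen (kg/ha/yr) is not mapped at scale, so it is
modelled: ordinal fertility classes 1–4 (1 = highest availability — the
orientation is configurable) are reclassified to 100/65/40/20 kg/ha/yr;
dividing by the 0–30 cm nitrogen pool (Σ content g/kg × bulk density kg/m³ ×
thickness m / 1000, in kg/m², × 10⁴ → kg/ha; layers crossing 30 cm are
truncated) yields a coarse pseudo-mineralization rate (1/yr). The rate is
regressed on mean annual temperature, annual precipitation, temperature
seasonality (sd of monthly mean temperature × 100) and soil pH.

The family and link are a design decision (unstated in the source method):
a **Gamma GLM with log link**, because rates are strictly positive with
multiplicative covariate effects. The reported diagnostic is deviance
explained, D² = 1 − residual deviance / null deviance. No covariate
transformations or interactions are used. Calibration requires ≥ 50 cells.

Per-simulation soil vectors use metadata verbatim where present, convert
descriptive water/fertility ratings through 5-level ordinal lookups
(editable defaults: very dry/dry/mesic/moist/wet → 40/80/120/160/200 mm WHC;
very poor … very rich → 20/40/65/100/120 kg N/ha/yr), and fill the remainder
from the nearest grid cell — nearest-center lookup without interpolation,
chosen for determinism at the 1-km scale the grids represent. Available N
falls back to pool × modelled rate. A missing field for a location outside
the grids is an error naming the field.

## Coverage analysis

Climate space is stratified by MAT (10 bins; edges −2, 2, 4, 6, 8, 10, 12,
14, 18 °C), annual precipitation (7 bins; 400, 550, 750, 1000, 1400,
2000 mm) and seasonality (7 bins; 200, 400, 500, 600, 700, 900). Soil space
by texture class, WHC (5 bins; 50, 100, 150, 180 mm) and available N (5
bins; 20, 40, 65, 100 kg/ha/yr). All interval lists reuse endpoints, so
every bin is half-open [low, high): a boundary value goes to the upper bin.

Texture uses a five-class scheme (1 coarse … 5 very fine) with configurable
clay/sand thresholds approximating the European Soil Database convention:
clay ≥ 60 → 5; clay ≥ 35 → 4; sand ≤ 15 → 3; clay < 18 and sand > 65 → 1;
else 2. (Descriptions of the scheme disagree on five vs. six classes; the
five-class orientation matching the class-map convention is implemented and
configurable.)

Coverage is the area-weighted percentage of reference cells whose stratum is
occupied by at least one simulation; cell areas are weighted by
cos(latitude). Simulations are assigned to climate strata via their grid
cell's values, which understates coverage when one simulation spans
gradients within a cell.

## Synthetic data: what it emulates, and what it does not

The generators provide every input with known ground truth.

*Weather.* Daily temperature is a sinusoidal seasonal cycle (amplitude
increasing with latitude) plus AR(1) noise (ρ = 0.75), centred on an annual
mean that follows the scenario's prescribed linear trend plus interannual
variability (sd 0.25 °C). Precipitation is Bernoulli–Gamma (wet-day
probability ~0.35, slightly winter-weighted; shape 0.7) rescaled so each
year's total matches the prescribed ANP times lognormal interannual noise
(sd 0.04). Radiation is a clear-sky seasonal curve damped 45 % on wet days;
VPD is Magnus saturation pressure times (1 − relative humidity), humidity
higher on wet days. Years have exactly 365 days, matching the output
schema's fixed 365 columns. All scenarios share one year range; splitting
historical and future eras would add bookkeeping without exercising any
additional code path.

Default scenario trends separate the members of one RCP by ±0.025 °C/yr and
∓0.003 fraction/yr. This spacing is deliberate: trajectory-recovery testing
presumes that noise stays below scenario separation, and a realized 30-year
OLS trend at the generator's interannual variability has a standard error of
roughly 0.5 °C/century — the chosen spacing keeps same-RCP members ≳3
standard errors apart. Real GCM ensembles are closer together and real
interannual variability is larger; recovery rates on real data would be
lower, which is exactly why the method keeps RCP/GCM hints when metadata
provides them.

*Simulation sets.* Each synthetic simulation is tied to one catalogue
trajectory through a true temperature offset (sd 0.7 °C) and precipitation
factor (log-sd 0.10), emulating the resolution mismatch between local
forcing and the gridded catalogue, plus small annual metadata noise
(0.05 °C, 1 %). Species shares follow a bounded random walk on the simplex
(an implicit remainder keeps sums ≤ 1), heights follow a saturating growth
curve with fixed min/mean/max ratios, and per-"model" reporting profiles
drop height statistics to emulate contributor heterogeneity. Soil metadata
is complete, ratings-only, or absent with fixed probabilities. The
generator does not emulate any real simulator's ecological behaviour,
management effects, disturbances, or measurement error structure — passing
tests demonstrate the harmonization machinery, not ecological fidelity.

*Soil grids.* Covariate fields are smooth latitudinal/longitudinal gradients
plus cell noise; the true pseudo-mineralization rate is exactly the Gamma
GLM inverse link applied to them (default coefficients −6.45, 0.09/°C,
5·10⁻⁴/mm, −5·10⁻⁴ per seasonality unit, 0.15/pH unit, chosen so true
available N spans all four fertility classes at realistic magnitudes). The
SQ1-style class at each cell is the reclassification value nearest to true
available N after multiplicative lognormal jitter (sd 0.15) emulating
fertility-map classification error. The jitter matters: it dithers the
4-level quantization, so the calibrated GLM recovers the smooth rate surface
rather than a staircase, as the end-to-end nitrogen recovery demonstrates
(median relative error ≈ 2 % at defaults).

*Height calibration.* Per-species truth is linear: dominant =
a·mean + b·max and max = c + d·mean. Stand-level spread of max around its
species line (`structure_sd`, default 1 m) is separate from observation
noise on dominant height (`noise_sd`): without the former, mean and max are
collinear and the dominant model is unidentifiable (see above). Mean heights
are drawn on 8–35 m so the max ≥ mean floor never binds systematically.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small instances — 2 × 2
climate cells × 30 years × 12 scenarios, 30 × 30 soil cells, 200 simulations
for recovery checks, 50 for pipeline runs — sizes at which every statistical
property under test is already well-resolved. Every random draw flows from
an explicit seed through `numpy` generators; per-simulation substreams are
derived by hashing the simulation id, so outputs are reproducible and
independent of processing order. Reruns with the same configuration and
seed reproduce state strings, year mappings and stored daily values exactly.

## Known limitations

* The allometric factors and the rating-conversion tables ship as documented
  placeholders; quantitative results that depend on them are only as good as
  the configured values.
* The mixed-model R² diagnostics on synthetic data say nothing about the
  fit quality achievable on real yield-table data.
* Trajectory selection assumes the annual metadata series is on the same
  calendar as the catalogue when calendar years are given; simulations
  indexed 1..N are matched against full-period trajectory trends.
* The coverage analysis inherits the grid-cell assignment bias described
  above and uses cos(latitude) area weights, adequate at the sub-degree
  scales involved.
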