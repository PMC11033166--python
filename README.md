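# forestharm

Harmonization pipeline for heterogeneous forest-simulation outputs.

Process-based forest models project stand development under climate change,
but every model reports different variables, height statistics, and climate
forcings, which makes cross-model syntheses hard. `forestharm` turns
contributed annual model outputs (species basal-area shares, canopy height
statistics, leaf area index) into a common database: one row per
simulation-year holding a **discrete vegetation state**, a harmonized
dominant height, a complete quantitative soil vector, and a standardized
daily climate series (temperature, precipitation, radiation, VPD), written
as one SQLite database per climate scenario. A coverage analysis reports how
much of a reference climate/soil space the simulations span.

## The core methods

**Discrete vegetation states.** A stand-year is encoded as
`<composition>_<LAI class>_<height bin>`:

* a species with share > 66 % of stand basal area is *dominant* (upper-case
  4-letter code, two genus + two epithet letters, e.g. *Picea abies* → PIAB);
  species with share ≥ 20 % are *admixed* (lower-case);
* LAI class 1 (sparse, LAI < 2), 2 (moderate, 2 ≤ LAI ≤ 4), 3 (dense, LAI > 4);
* dominant height grouped into 2-m bins.

`PIABfasy_3_20_22` is a spruce-dominated stand with admixed beech, a dense
canopy, and a dominant height between 20 and 22 m.

**Dominant height.** Models report any subset of {min, mean, max} canopy
height. A missing mean is filled as (min + max)/2; a missing maximum is
predicted from the mean with a linear mixed model (per-species random
intercept and slope). Dominant height is then obtained from a per-species
allometric factor on maximum height (for the six species with published
yield-table factors) or from a linear mixed model
`dominant ~ mean + max` with per-species random slopes, and finally clamped
to [0.8·max, max].

**Climate matching.** Each simulation carries only annual temperature and
precipitation; it is matched to a catalogue of daily trajectories
(historical + RCP2.6/4.5/8.5 × 3 GCMs on a 0.11° grid) by minimizing the
trend index ΔT + 0.1·ΔP (°C and % precipitation change per century) among
hint-compatible trajectories at the nearest grid cell. The chosen trajectory
is level-adjusted (additive in temperature, multiplicative in
precipitation), and every simulation year receives the daily data of one of
its three best-matching scenario years (index |ΔT| + 0.1·|ΔP %|, sampled
uniformly with a seeded generator).

**Soil.** Ordinal fertility classes are reclassified to 100/65/40/20
kg N/ha/yr, divided by the 0–30 cm nitrogen pool to form a
pseudo-mineralization rate (1/yr), and regressed on mean annual temperature,
annual precipitation, temperature seasonality and pH with a Gamma GLM (log
link). Pool × modelled rate gives plant-available nitrogen wherever no
measurement exists; WHC, texture and depth are filled from gridded layers.

A synthetic-data module generates scenario catalogues, contributor bundles,
soil grids and height-calibration tables with known ground truth, so every
stage is testable without external data.

## Worked example

```bash
harmonize synth --out demo --seed 2 --n-sims 3   # synthetic bundle
harmonize run --config demo/config.yaml
```

prints

```
wrote 90 rows (90 validated simulation-years, 19 distinct states) to demo/harmonized
coverage: climate 31.4%, soil 6.6%
```

Three 30-year simulations became 90 database rows (conservation: rows out =
validated simulation-years in), collapsing into 19 distinct vegetation
states; the three locations' strata cover 31.4 % of the synthetic reference
climate space and 6.6 % of its soil space. Each per-scenario SQLite file in
`demo/harmonized/` has the full published schema (identity, state, soil
vector, scenario, `tas_1`…`vpd_365`), e.g.:

```python
>>> from forestharm import ingest
>>> df = ingest.read_harmonized_db("demo/harmonized/harmonized_historical_GCM-A.sqlite")
>>> df.loc[0, ["SimulationID", "Year", "vegetation_state", "dominant_height", "LAI"]]
SimulationID                 sim0002
Year                            2015
vegetation_state    qurofasy_2_16_18
dominant_height            16.652834
LAI                         3.329729
```

`qurofasy_2_16_18` reads: no dominant species; oak and beech admixed (each
≥ 20 % of basal area); moderate canopy (LAI class 2); dominant height in the
16–18 m bin.

The same operations are available as a library — see
`forestharm.states.encode_state`, `forestharm.climate.select_trajectory`,
`forestharm.soil.fit_rate_glm`, `forestharm.pipeline.run`.

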