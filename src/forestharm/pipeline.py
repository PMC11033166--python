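"""End-to-end harmonization: contributions in, per-scenario databases out.

For every validated simulation the pipeline (i) encodes each year's
vegetation state, (ii) harmonizes dominant height, (iii) selects, adjusts
and year-matches a catalogue climate trajectory, (iv) completes the soil
vector, and (v) writes one row per simulation-year into the SQLite database
of the matched scenario. A coverage report over climate and soil strata and
the resolved configuration accompany the outputs.

Per-simulation randomness (the 3-best-year sampling) is derived from the
pipeline seed and a CRC32 hash of the simulation id, so results are
reproducible regardless of processing order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import climate, coverage as cov, heights, ingest, soil, states
from .config import PipelineConfig
from .synthetic import ScenarioCatalogue

__all__ = ["PipelineResult", "run", "simulation_rng"]

log = logging.getLogger("forestharm")


@dataclass
class PipelineResult:
    """Summary of one pipeline run."""

    out_dir: Path
    scenario_rows: dict[str, int]
    validated_years: int
    excluded: list[str]
    climate_coverage: float
    soil_coverage: float
    distinct_states: int
    db_paths: dict[str, Path] = field(default_factory=dict)


def simulation_rng(seed: int, simulation_id: str) -> np.random.Generator:
    """Independent, order-insensitive random substream for one simulation."""
    return np.random.default_rng([seed, zlib.crc32(simulation_id.encode())])


def _dominant_species_name(shares: dict[str, float], threshold: float) -> str | None:
    for name, s in shares.items():
        if s > threshold:
            return name
    return None


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full harmonization under one configuration and seed."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    catalogue = ScenarioCatalogue.from_parquet(config.catalogue)
    grids = xr.open_dataset(config.soil_grids, engine="scipy") if str(
        config.soil_grids
    ).endswith(".nc") else xr.open_dataset(config.soil_grids)
    calibration = pd.read_csv(config.height_calibration)

    log.info("calibrating height models on %d rows", len(calibration))
    dom_model = heights.fit_dominant_model(calibration)
    dom_model.allometric_factors = dict(config.allometric_factors)
    max_model = heights.fit_max_from_mean(calibration)

    log.info("calibrating soil rate GLM")
    rate_table = soil.rates_from_grids(grids, {int(k): v for k, v in config.fertility_reclass.items()})
    rate_model = soil.fit_rate_glm(rate_table["rate"], rate_table)

    buckets: dict[str, list[dict]] = {}
    all_meta: dict[str, ingest.SimulationMetadata] = {}
    soil_vectors: dict[str, soil.SoilVector] = {}
    occupied_climate: set = set()
    occupied_soil: set = set()
    excluded: list[str] = []
    validated_years = 0

    for contrib in config.contributions:
        records, metadata = ingest.read_contribution(contrib["sim"], contrib["meta"])
        report = ingest.validate_contribution(records, metadata)
        bad_ids = {sid for c in report.failures() for sid in c.offending}
        for c in report.failures():
            log.warning("validation %s failed for %s", c.name, c.offending)
        excluded.extend(sorted(bad_ids))

        by_sim: dict[str, list[ingest.SimulationRecord]] = {}
        for r in records:
            if r.simulation_id not in bad_ids and r.simulation_id in metadata:
                by_sim.setdefault(r.simulation_id, []).append(r)

        for sim_id, recs in sorted(by_sim.items()):
            meta = metadata[sim_id]
            try:
                rows, sim_soil = _harmonize_simulation(
                    sim_id, recs, meta, catalogue, grids, dom_model, max_model, rate_model, config
                )
            except Exception as exc:
                log.warning("simulation %s failed: %s", sim_id, exc)
                excluded.append(sim_id)
                continue
            scenario = rows[0]["Scenario"]
            buckets.setdefault(scenario, []).extend(rows)
            validated_years += len(rows)
            all_meta[sim_id] = meta
            soil_vectors[sim_id] = sim_soil
            cell = grids.sel(lat=meta.latitude, lon=meta.longitude, method="nearest")
            occupied_climate.add(
                cov.climate_stratum(
                    float(cell["mat"]), float(cell["anp"]), float(cell["seasonality"])
                )
            )
            sv = soil_vectors[sim_id]
            occupied_soil.add(
                cov.soil_stratum(
                    cov.texture_class(sv.sand, sv.silt, sv.clay), sv.whc, sv.available_n
                )
            )

    db_paths: dict[str, Path] = {}
    scenario_rows: dict[str, int] = {}
    all_states: set[str] = set()
    for scenario, rows in sorted(buckets.items()):
        df = pd.DataFrame(rows)
        path = out_dir / f"harmonized_{scenario}.sqlite"
        ingest.write_harmonized_db(df, scenario, path)
        db_paths[scenario] = path
        scenario_rows[scenario] = len(df)
        all_states.update(df["vegetation_state"].unique())
        log.info("wrote %d rows to %s", len(df), path)

    ingest.write_metadata_db(all_meta, soil_vectors, out_dir / "metadata.sqlite")

    clim_ref, soil_ref = cov.reference_from_grids(grids)
    climate_coverage = cov.coverage_fraction(occupied_climate, clim_ref)
    soil_coverage = cov.coverage_fraction(occupied_soil, soil_ref)
    pd.DataFrame(
        {
            "space": ["climate", "soil"],
            "occupied_strata": [len(occupied_climate), len(occupied_soil)],
            "covered_area_pct": [climate_coverage, soil_coverage],
        }
    ).to_csv(out_dir / "coverage.csv", index=False)
    log.info("coverage: climate %.1f%%, soil %.1f%%", climate_coverage, soil_coverage)

    config.to_yaml(out_dir / "resolved_config.yaml")
    return PipelineResult(
        out_dir=out_dir,
        scenario_rows=scenario_rows,
        validated_years=validated_years,
        excluded=sorted(set(excluded)),
        climate_coverage=climate_coverage,
        soil_coverage=soil_coverage,
        distinct_states=len(all_states),
        db_paths=db_paths,
    )


def _harmonize_simulation(
    sim_id: str,
    recs: list[ingest.SimulationRecord],
    meta: ingest.SimulationMetadata,
    catalogue: ScenarioCatalogue,
    grids,
    dom_model: heights.DominantHeightModel,
    max_model: heights.MaxHeightModel,
    rate_model: soil.RateGLM,
    config: PipelineConfig,
) -> tuple[list[dict], soil.SoilVector]:
    recs = sorted(recs, key=lambda r: r.year)
    sim_years = [r.year for r in recs]

    scenario = climate.select_trajectory(meta, catalogue, weight=config.matching_weight)
    cell = catalogue.nearest_cell(meta.latitude, meta.longitude)
    traj = catalogue.trajectories[(scenario, cell.cell_id)]
    adjusted, delta, factor = climate.adjust_trajectory(
        traj,
        float(meta.annual_temperature.mean()),
        float(meta.annual_precipitation.mean()),
        sim_years=sim_years,
    )
    rng = simulation_rng(config.seed, sim_id)
    sim_annual = pd.DataFrame(
        {
            "temperature": meta.annual_temperature.to_numpy(),
            "precipitation": meta.annual_precipitation.to_numpy(),
        },
        index=meta.annual_temperature.index,
    )
    mapping = climate.match_years(sim_annual, adjusted, rng, weight=config.matching_weight)

    sv = soil.complete_soil_vector(
        meta,
        grids,
        rate_model,
        water_rating=config.water_rating_lookup,
        fertility_rating=config.fertility_rating_lookup,
    )

    rows = []
    for r in recs:
        dominant_name = _dominant_species_name(r.species_shares, config.dominance_threshold)
        stats = heights.HeightStatistics(min=r.height_min, mean=r.height_mean, max=r.height_max)
        dom_h = heights.dominant_height(
            stats, dominant_name, dom_model, max_model, allometric_factors=config.allometric_factors
        )
        state = states.VegetationState(
            composition=states.classify_composition(
                r.species_shares,
                dominance_threshold=config.dominance_threshold,
                admixture_threshold=config.admixture_threshold,
            ),
            lai_class=states.lai_class(r.lai, edges=config.lai_edges),
            height_bin=states.height_bin(dom_h, width=config.height_bin_width),
        )
        daily = climate.assemble_daily(adjusted, mapping, r.year)
        row = {
            "SourceID": r.source_id,
            "SimulationID": sim_id,
            "Year": r.year,
            "vegetation_state": states.encode_state(state),
            "dominant_height": dom_h,
            "LAI": r.lai,
            "WHC": sv.whc,
            "TextureSand": sv.sand,
            "TextureSilt": sv.silt,
            "TextureClay": sv.clay,
            "SoilDepth": sv.depth,
            "AvailableNitrogen": sv.available_n,
            "Scenario": scenario,
        }
        for v in ("tas", "prec", "rad", "vpd"):
            for d in range(365):
                row[f"{v}_{d + 1}"] = float(daily[v][d])
        rows.append(row)
    return rows, sv
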