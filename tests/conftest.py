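"""Shared synthetic fixtures; everything is generated at test time."""

from __future__ import annotations

import pytest

from forestharm import synthetic as syn

SPECIES_POOL = [
    "Picea abies",
    "Fagus sylvatica",
    "Pinus sylvestris",
    "Quercus robur",
    "Abies alba",
]


@pytest.fixture(scope="session")
def grid_spec():
    return syn.GridSpec(47.0, 47.22, 11.0, 11.22)


@pytest.fixture(scope="session")
def catalogue(grid_spec):
    """Default scenario set: historical + 3 RCPs × 3 GCMs, 30 years, 2×2 cells."""
    return syn.gen_scenario_catalogue(
        3, ["rcp26", "rcp45", "rcp85"], range(2015, 2045), grid_spec, seed=11
    )


@pytest.fixture(scope="session")
def sim_set(catalogue):
    """30 synthetic simulations with their ground truth."""
    return syn.gen_simulation_set(catalogue, 30, SPECIES_POOL, seed=11)


@pytest.fixture(scope="session")
def soil_grids():
    """Soil/climate grid stack (30 × 30 cells) with GLM ground truth."""
    return syn.gen_soil_grids(syn.GridSpec(45.0, 48.3, 8.0, 11.3, resolution=0.11), seed=11)


@pytest.fixture(scope="session")
def height_truth():
    return syn.default_height_truth(SPECIES_POOL, seed=11)


@pytest.fixture(scope="session")
def calibration_noisy(height_truth):
    return syn.gen_height_calibration(
        300, SPECIES_POOL, coeff_truth=height_truth, noise_sd=0.5, structure_sd=1.0, seed=11
    )
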