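"""Generators: cardinality, determinism, trend realism, truth completeness."""

import numpy as np
import pandas as pd
import pytest

from forestharm import synthetic as syn
from forestharm.synthetic import (
    GridSpec,
    HeightProfile,
    RateCoefficients,
    SimNoise,
    default_trend_spec,
    gen_height_calibration,
    gen_scenario_catalogue,
    gen_simulation_set,
    gen_soil_grids,
)


def test_catalogue_default_configuration_has_12_scenarios(catalogue):
    assert len(catalogue.scenario_ids) == 12
    for cell in catalogue.cells:
        per_cell = [k for k in catalogue.trajectories if k[1] == cell.cell_id]
        assert len(per_cell) == 12


def test_catalogue_degenerate_historical_only(grid_spec):
    cat = gen_scenario_catalogue(1, [], range(2015, 2020), grid_spec, seed=1)
    assert cat.scenario_ids == ["historical_GCM-A"]


def test_catalogue_seeded_determinism(grid_spec):
    a = gen_scenario_catalogue(2, ["rcp45"], range(2015, 2022), grid_spec, seed=7)
    b = gen_scenario_catalogue(2, ["rcp45"], range(2015, 2022), grid_spec, seed=7)
    assert a.scenario_ids == b.scenario_ids
    for key in a.trajectories:
        for v in ("tas", "prec", "rad", "vpd"):
            assert np.array_equal(getattr(a.trajectories[key], v), getattr(b.trajectories[key], v))


def test_catalogue_invariants(catalogue):
    for traj in catalogue.trajectories.values():
        assert traj.tas.shape == (30, 365)
        assert (traj.prec >= 0).all() and (traj.vpd >= 0).all()


def test_catalogue_realized_trends_match_spec(catalogue):
    spec = default_trend_spec(["GCM-A", "GCM-B", "GCM-C"], ["rcp26", "rcp45", "rcp85"])
    for sid in catalogue.scenario_ids:
        traj = catalogue.trajectories[(sid, catalogue.cells[0].cell_id)]
        years = traj.years.astype(float)
        slope_t = np.polyfit(years, traj.annual_mat, 1)[0]
        anp = traj.annual_anp
        slope_p = np.polyfit(years, anp, 1)[0] / anp.mean()
        # tolerances ≈ 4 standard errors of a 30-year OLS slope at the
        # generator's interannual variability
        assert abs(slope_t - spec[sid][0]) < 0.027
        assert abs(slope_p - spec[sid][1]) < 0.007


def test_grid_spec_errors():
    with pytest.raises(ValueError):
        GridSpec(47.0, 47.0, 11.0, 11.2)
    with pytest.raises(ValueError):
        GridSpec(47.0, 47.2, 11.0, 11.2, resolution=-0.1)
    with pytest.raises(ValueError):
        gen_scenario_catalogue(1, [], range(0), GridSpec(47.0, 47.2, 11.0, 11.2))


def test_catalogue_parquet_round_trip(catalogue, tmp_path):
    path = tmp_path / "cat.parquet"
    catalogue.to_parquet(path)
    back = syn.ScenarioCatalogue.from_parquet(path)
    assert back.scenario_ids == catalogue.scenario_ids
    assert back.period == catalogue.period
    key = ("rcp45_GCM-B", catalogue.cells[0].cell_id)
    assert np.allclose(back.trajectories[key].tas, catalogue.trajectories[key].tas)
    assert np.allclose(back.trajectories[key].prec, catalogue.trajectories[key].prec)


def test_simulation_set_identity_forcing(catalogue):
    """Zero offset/factor/noise → simulation summaries equal the trajectory's."""
    zero = SimNoise(offset_sd=0.0, log_factor_sd=0.0, temperature_sd=0.0, precipitation_cv=0.0)
    sim_df, meta_df, truth = gen_simulation_set(
        catalogue, 5, ["Picea abies"], seed=3, noise=zero
    )
    stand = sim_df[sim_df["species"].isna() | (sim_df["species"] == "")]
    for sim_id, t in truth.simulations.items():
        assert t.temperature_offset == 0.0 and t.precipitation_factor == 1.0
        traj = catalogue.trajectories[(t.scenario_id, t.cell_id)]
        rows = stand[stand["simulation_id"] == sim_id].sort_values("year")
        assert np.array_equal(rows["annual_temperature"].to_numpy(), traj.annual_mat)
        assert np.array_equal(rows["annual_precipitation"].to_numpy(), traj.annual_anp)


def test_simulation_set_shares_on_simplex(sim_set):
    sim_df, _, _ = sim_set
    species_rows = sim_df[sim_df["species"].notna() & (sim_df["species"] != "")]
    sums = species_rows.groupby(["simulation_id", "year"])["share"].sum()
    assert (sums <= 1 + 1e-9).all()
    assert (species_rows["share"] >= 0).all()


def test_simulation_set_truth_completeness(sim_set):
    sim_df, meta_df, truth = sim_set
    sim_ids = set(sim_df["simulation_id"])
    assert set(truth.simulations) == sim_ids == set(meta_df["simulation_id"])
    assert len(meta_df) == len(truth.simulations)


def test_simulation_set_profile_propagation(catalogue):
    mean_only = [HeightProfile("mean-only", frozenset({"mean"}))]
    sim_df, meta_df, _ = gen_simulation_set(
        catalogue, 8, ["Picea abies", "Fagus sylvatica"], profiles=mean_only, seed=4
    )
    assert (meta_df["model_name"] == "mean-only").all()
    stand = sim_df[sim_df["species"].isna() | (sim_df["species"] == "")]
    assert stand["height_mean"].notna().all()
    assert stand["height_min"].isna().all() and stand["height_max"].isna().all()


def test_simulation_set_height_ordering_and_lai(sim_set):
    sim_df, _, _ = sim_set
    stand = sim_df[sim_df["species"].isna() | (sim_df["species"] == "")]
    present = stand.dropna(subset=["height_min", "height_mean", "height_max"])
    assert (present["height_min"] <= present["height_mean"] + 1e-9).all()
    assert (present["height_mean"] <= present["height_max"] + 1e-9).all()
    assert (stand["lai"] >= 0).all()


def test_empty_profile_rejected():
    with pytest.raises(ValueError):
        HeightProfile("nothing", frozenset())


def test_soil_grids_texture_closure_and_determinism():
    spec = GridSpec(46.0, 46.9, 9.0, 9.9, resolution=0.11)
    a, truth_a = gen_soil_grids(spec, seed=5)
    b, _ = gen_soil_grids(spec, seed=5)
    assert float(np.abs(a["sand"] + a["silt"] + a["clay"] - 100).max()) < 1e-6
    for v in ("sq1", "whc", "ph", "n_content"):
        assert np.array_equal(a[v].values, b[v].values)
    assert (truth_a.rate_true > 0).all()


def test_soil_grids_intercept_only_truth_is_constant():
    spec = GridSpec(46.0, 46.5, 9.0, 9.5, resolution=0.11)
    flat = RateCoefficients(const=-4.0, mat=0.0, anp=0.0, seasonality=0.0, ph=0.0)
    _, truth = gen_soil_grids(spec, glm_truth=flat, seed=6)
    assert np.allclose(truth.rate_true, np.exp(-4.0))


def test_soil_grids_truth_matches_inverse_link():
    spec = GridSpec(46.0, 46.5, 9.0, 9.5, resolution=0.11)
    coeff = RateCoefficients()
    ds, truth = gen_soil_grids(spec, glm_truth=coeff, seed=7)
    expected = coeff.rate(ds["mat"].values, ds["anp"].values, ds["seasonality"].values, ds["ph"].values)
    assert np.allclose(truth.rate_true, expected)
    assert np.allclose(truth.available_n_true, truth.rate_true * (
        (ds["n_content"].values * ds["bulk_density"].values
         * np.diff(np.array([0.0, 0.05, 0.15, 0.30]))[:, None, None] / 1000.0).sum(axis=0) * 1e4
    ))


def test_height_calibration_ordering(calibration_noisy):
    t = calibration_noisy
    assert (t["height_min"] <= t["height_mean"] + 1e-9).all()
    assert (t["height_mean"] <= t["height_max"] + 1e-9).all()
    assert (t[["height_min", "height_mean", "height_max", "dominant_height"]] > 0).all().all()


def test_height_calibration_preconditions():
    with pytest.raises(ValueError):
        gen_height_calibration(1, ["Picea abies"])
    with pytest.raises(ValueError):
        gen_height_calibration(10, ["Picea abies"], noise_sd=-1.0)
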