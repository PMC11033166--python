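"""Trajectory selection, level adjustment, year matching, daily assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from forestharm import climate as cli, synthetic as syn
from forestharm.climate import (
    adjust_trajectory,
    assemble_daily,
    candidate_scenarios,
    match_years,
    select_trajectory,
    trajectory_distance,
    trend_slopes,
    year_distance,
)


def test_trend_slopes_exact_linear():
    years = np.arange(2000, 2020)
    t = pd.Series(10 + 0.1 * (years - 2000), index=years)
    p = pd.Series(np.full(len(years), 800.0), index=years)
    slope_t, slope_p = trend_slopes(t, p)
    assert slope_t == pytest.approx(0.1, abs=1e-12)
    assert slope_p == pytest.approx(0.0, abs=1e-12)


def test_trend_slopes_match_normal_equations():
    rng = np.random.default_rng(5)
    years = np.arange(1990, 2030)
    t = pd.Series(rng.normal(8, 1, len(years)), index=years)
    p = pd.Series(rng.uniform(500, 900, len(years)), index=years)
    slope_t, slope_p = trend_slopes(t, p)
    x = years - years.mean()
    assert slope_t == pytest.approx(float((x * (t - t.mean())).sum() / (x**2).sum()), rel=1e-9)
    assert slope_p == pytest.approx(
        float((x * (p - p.mean())).sum() / (x**2).sum()) / p.mean(), rel=1e-9
    )


def test_trend_slopes_preconditions():
    idx = [2000, 2001]
    with pytest.raises(ValueError):
        trend_slopes(pd.Series([1.0, 2.0], index=idx), pd.Series([1.0, 2.0], index=idx))
    idx3 = [2000, 2000, 2000]
    with pytest.raises(ValueError):
        trend_slopes(pd.Series([1.0, 2.0, 3.0], index=idx3), pd.Series([1.0, 2.0, 3.0], index=idx3))


def test_trajectory_distance_units():
    assert trajectory_distance((0.01, 0.0), (0.01, 0.0)) == 0.0
    # 1 °C per century temperature-slope difference → 1.0
    assert trajectory_distance((0.01, 0.0), (0.0, 0.0)) == pytest.approx(1.0)
    # 10 % precipitation change per century → 1.0 (the 0.1 weight)
    assert trajectory_distance((0.0, 0.001), (0.0, 0.0)) == pytest.approx(1.0)


def test_trajectory_distance_pseudometric():
    rng = np.random.default_rng(2)
    for _ in range(100):
        a = tuple(rng.normal(0, 0.01, 2))
        b = tuple(rng.normal(0, 0.01, 2))
        assert trajectory_distance(a, b) >= 0
        assert trajectory_distance(a, b) == pytest.approx(trajectory_distance(b, a))
        assert trajectory_distance(a, a) == 0.0


def test_year_distance_formula():
    assert year_distance((10.0, 800.0), (10.0, 800.0)) == 0.0
    assert year_distance((11.0, 800.0), (10.0, 800.0)) == pytest.approx(1.0)
    assert year_distance((10.0, 880.0), (10.0, 800.0)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        year_distance((10.0, 0.0), (10.0, 800.0))


def test_select_trajectory_recovers_source(catalogue, sim_set):
    """Noise below scenario separation: every simulation finds its trajectory."""
    from forestharm import ingest

    sim_df, meta_df, truth = sim_set
    import tempfile, os

    with tempfile.TemporaryDirectory() as d:
        sp, mp = os.path.join(d, "s.csv"), os.path.join(d, "m.csv")
        sim_df.to_csv(sp, index=False)
        meta_df.to_csv(mp, index=False)
        _, metas = ingest.read_contribution(sp, mp)
    hits = sum(
        select_trajectory(m, catalogue) == truth.simulations[sid].scenario_id
        for sid, m in metas.items()
    )
    assert hits == len(metas)


def test_hint_restricts_candidates(catalogue, sim_set):
    class Meta:
        trajectory_family = "RCP"
        rcp_hint = "rcp26"
        gcm_hint = None

    cands = candidate_scenarios(Meta(), catalogue)
    assert cands == ["rcp26_GCM-A", "rcp26_GCM-B", "rcp26_GCM-C"]

    class Baseline:
        trajectory_family = "baseline"
        rcp_hint = None
        gcm_hint = None

    assert all(c.startswith("historical") for c in candidate_scenarios(Baseline(), catalogue))

    class Impossible:
        trajectory_family = "RCP"
        rcp_hint = "rcp60"
        gcm_hint = None

    with pytest.raises(ValueError):
        candidate_scenarios(Impossible(), catalogue)


def test_select_trajectory_tie_breaks_lexicographically(catalogue):
    """Two identical candidate trajectories → the smaller scenario id wins."""
    cell = catalogue.cells[0]
    base = catalogue.trajectories[("rcp45_GCM-B", cell.cell_id)]
    twin_a = base.replace(scenario_id="rcp99_GCM-A")
    twin_b = base.replace(scenario_id="rcp99_GCM-B")
    tiny = syn.ScenarioCatalogue(
        trajectories={("rcp99_GCM-A", cell.cell_id): twin_a, ("rcp99_GCM-B", cell.cell_id): twin_b},
        cells=[cell],
        period=catalogue.period,
    )

    class Meta:
        trajectory_family = "RCP"
        rcp_hint = None
        gcm_hint = None
        latitude = cell.lat
        longitude = cell.lon
        annual_temperature = pd.Series(base.annual_mat, index=base.years)
        annual_precipitation = pd.Series(base.annual_anp, index=base.years)

    assert select_trajectory(Meta(), tiny) == "rcp99_GCM-A"


def test_adjust_trajectory_exactness(catalogue):
    traj = catalogue.trajectories[("rcp85_GCM-C", catalogue.cells[1].cell_id)]
    adjusted, delta, factor = adjust_trajectory(traj, 10.0, 900.0)
    assert adjusted.annual_mat.mean() == pytest.approx(10.0, abs=1e-9)
    assert adjusted.annual_anp.mean() == pytest.approx(900.0, abs=1e-9)
    assert np.allclose(adjusted.tas, traj.tas + delta)
    assert np.allclose(adjusted.prec, traj.prec * factor)
    assert adjusted.rad is traj.rad and adjusted.vpd is traj.vpd  # untouched


def test_adjust_trajectory_identity(catalogue):
    traj = catalogue.trajectories[("historical_GCM-A", catalogue.cells[0].cell_id)]
    adjusted, delta, factor = adjust_trajectory(
        traj, float(traj.annual_mat.mean()), float(traj.annual_anp.mean())
    )
    assert delta == pytest.approx(0.0, abs=1e-12) and factor == pytest.approx(1.0, abs=1e-15)
    assert np.array_equal(adjusted.tas, traj.tas)
    assert np.array_equal(adjusted.prec, traj.prec)


def test_match_years_zero_distance_year_is_candidate(catalogue):
    traj = catalogue.trajectories[("rcp26_GCM-A", catalogue.cells[0].cell_id)]
    y = traj.years[5]
    sim_annual = pd.DataFrame(
        {"temperature": [traj.annual_mat[5]], "precipitation": [traj.annual_anp[5]]}, index=[int(y)]
    )
    picks = {
        match_years(sim_annual, traj, np.random.default_rng(s))[int(y)] for s in range(60)
    }
    assert int(y) in picks and len(picks) <= 3


def test_match_years_deterministic_under_seed(catalogue):
    traj = catalogue.trajectories[("rcp26_GCM-B", catalogue.cells[0].cell_id)]
    sim_annual = pd.DataFrame(
        {"temperature": traj.annual_mat + 0.2, "precipitation": traj.annual_anp * 1.01},
        index=traj.years,
    )
    m1 = match_years(sim_annual, traj, np.random.default_rng(99))
    m2 = match_years(sim_annual, traj, np.random.default_rng(99))
    assert m1 == m2


def test_match_years_samples_uniformly(catalogue):
    """The 3 best years are drawn with equal probability (χ², α = 0.01)."""
    traj = catalogue.trajectories[("rcp45_GCM-A", catalogue.cells[0].cell_id)]
    sim_annual = pd.DataFrame(
        {"temperature": [traj.annual_mat[10]], "precipitation": [traj.annual_anp[10]]},
        index=[int(traj.years[10])],
    )
    rng = np.random.default_rng(7)
    draws = [match_years(sim_annual, traj, rng)[int(traj.years[10])] for _ in range(3000)]
    counts = pd.Series(draws).value_counts()
    assert len(counts) == 3
    assert sps.chisquare(counts.to_numpy()).pvalue > 0.01


def test_assemble_daily(catalogue):
    traj = catalogue.trajectories[("rcp85_GCM-A", catalogue.cells[0].cell_id)]
    year = int(traj.years[3])
    daily = assemble_daily(traj, {2020: year}, 2020)
    assert all(len(v) == 365 for v in daily.values())
    assert np.array_equal(daily["tas"], traj.tas[3])
    assert (daily["prec"] >= 0).all()
    assert daily["prec"].sum() == pytest.approx(traj.annual_anp[3])
    with pytest.raises(KeyError):
        assemble_daily(traj, {2020: year}, 2021)
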