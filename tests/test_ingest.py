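"""Contribution parsing/validation and SQLite round trips."""

import numpy as np
import pandas as pd
import pytest

from forestharm import ingest
from forestharm.ingest import (
    CLIMATE_COLUMNS,
    TABLE1_COLUMNS,
    SchemaError,
    read_contribution,
    read_harmonized_db,
    validate_contribution,
    write_harmonized_db,
)


@pytest.fixture(scope="module")
def contribution(sim_set, tmp_path_factory):
    sim_df, meta_df, _ = sim_set
    d = tmp_path_factory.mktemp("contrib")
    sim_path, meta_path = d / "sim.csv", d / "meta.csv"
    sim_df.to_csv(sim_path, index=False)
    meta_df.to_csv(meta_path, index=False)
    return sim_path, meta_path


def test_round_trip_from_generator(contribution, sim_set):
    sim_df, meta_df, _ = sim_set
    records, metadata = read_contribution(*contribution)
    stand_rows = sim_df[sim_df["species"].isna() | (sim_df["species"] == "")]
    assert len(records) == len(stand_rows)
    assert set(metadata) == set(meta_df["simulation_id"])
    r = records[0]
    src = stand_rows[(stand_rows["simulation_id"] == r.simulation_id) & (stand_rows["year"] == r.year)].iloc[0]
    assert r.lai == pytest.approx(src["lai"])
    m = metadata[r.simulation_id]
    assert m.annual_temperature.loc[r.year] == pytest.approx(src["annual_temperature"])
    assert sum(r.species_shares.values()) <= 1 + 1e-9


def test_missing_lai_column_is_schema_error(contribution, tmp_path):
    sim = pd.read_csv(contribution[0]).drop(columns=["lai"])
    p = tmp_path / "nolai.csv"
    sim.to_csv(p, index=False)
    with pytest.raises(SchemaError, match="lai"):
        read_contribution(p, contribution[1])


def test_missing_all_height_columns_is_schema_error(contribution, tmp_path):
    sim = pd.read_csv(contribution[0]).drop(columns=["height_min", "height_mean", "height_max"])
    p = tmp_path / "noheights.csv"
    sim.to_csv(p, index=False)
    with pytest.raises(SchemaError, match="height"):
        read_contribution(p, contribution[1])


def test_empty_data_file_with_header(contribution, tmp_path):
    sim = pd.read_csv(contribution[0]).iloc[:0]
    meta = pd.read_csv(contribution[1]).iloc[:0]
    sp, mp = tmp_path / "s.csv", tmp_path / "m.csv"
    sim.to_csv(sp, index=False)
    meta.to_csv(mp, index=False)
    records, metadata = read_contribution(sp, mp)
    assert records == [] and metadata == {}


def test_unparseable_numeric_reports_row(contribution, tmp_path):
    sim = pd.read_csv(contribution[0])
    sim.loc[3, "lai"] = "not-a-number"
    p = tmp_path / "bad.csv"
    sim.to_csv(p, index=False)
    with pytest.raises(ingest.RowParseError, match="row 3"):
        read_contribution(p, contribution[1])


def test_validation_passes_on_generator_output(contribution):
    records, metadata = read_contribution(*contribution)
    report = validate_contribution(records, metadata)
    assert report.passed and report.failures() == []


def test_validation_flags_metadata_mismatch(contribution):
    records, metadata = read_contribution(*contribution)
    victim = records[0].simulation_id
    pruned = {k: v for k, v in metadata.items() if k != victim}
    report = validate_contribution(records, pruned)
    check = {c.name: c for c in report.checks}["id_match"]
    assert not check.passed and victim in check.offending


def test_validation_flags_year_gap(contribution):
    records, metadata = read_contribution(*contribution)
    victim = records[0].simulation_id
    thinned = [r for r in records if not (r.simulation_id == victim and r.year == records[0].year + 1)]
    report = validate_contribution(thinned, metadata)
    check = {c.name: c for c in report.checks}["annual_continuity"]
    assert not check.passed and victim in check.offending


def test_validation_flags_functional_type_labels(contribution):
    records, metadata = read_contribution(*contribution)
    records[0].species_shares["broadleaf"] = 0.1
    report = validate_contribution(records, metadata)
    check = {c.name: c for c in report.checks}["species_level"]
    assert not check.passed and records[0].simulation_id in check.offending
    del records[0].species_shares["broadleaf"]


def test_validation_flags_missing_indicator(contribution):
    records, metadata = read_contribution(*contribution)
    victim = records[0].simulation_id
    mutated = [
        ingest.SimulationRecord(
            r.source_id, r.simulation_id, r.year, {}, r.height_min, r.height_mean, r.height_max, r.lai
        )
        if r.simulation_id == victim
        else r
        for r in records
    ]
    report = validate_contribution(mutated, metadata)
    check = {c.name: c for c in report.checks}["required_indicators"]
    assert not check.passed and victim in check.offending


def _harmonized_frame(n=20, scenario="rcp45_GCM-B", seed=0):
    rng = np.random.default_rng(seed)
    base = {
        "SourceID": ["t"] * n,
        "SimulationID": [f"sim{i % 4}" for i in range(n)],
        "Year": list(range(2000, 2000 + n)),
        "vegetation_state": ["PIABfasy_3_20_22"] * n,
        "dominant_height": rng.uniform(5, 35, n),
        "LAI": rng.uniform(0, 6, n),
        "WHC": rng.uniform(40, 220, n),
        "TextureSand": [40.0] * n,
        "TextureSilt": [40.0] * n,
        "TextureClay": [20.0] * n,
        "SoilDepth": rng.uniform(300, 1500, n),
        "AvailableNitrogen": rng.uniform(20, 110, n),
        "Scenario": [scenario] * n,
    }
    clim = {c: rng.uniform(0, 10, n) for c in CLIMATE_COLUMNS}
    return pd.DataFrame({**base, **clim})


def test_harmonized_db_round_trip(tmp_path):
    df = _harmonized_frame(100)
    path = tmp_path / "db.sqlite"
    write_harmonized_db(df, "rcp45_GCM-B", path)
    back = read_harmonized_db(path)
    assert list(back.columns) == TABLE1_COLUMNS
    pd.testing.assert_frame_equal(back, df[TABLE1_COLUMNS], check_dtype=False)


def test_harmonized_db_rejects_mixed_scenarios(tmp_path):
    df = pd.concat([_harmonized_frame(5, "rcp45_GCM-B"), _harmonized_frame(5, "rcp26_GCM-A")])
    with pytest.raises(ValueError, match="scenario"):
        write_harmonized_db(df, "rcp45_GCM-B", tmp_path / "db.sqlite")


def test_harmonized_db_empty_keeps_schema(tmp_path):
    path = tmp_path / "empty.sqlite"
    write_harmonized_db(_harmonized_frame(0).iloc[:0], "rcp45_GCM-B", path)
    back = read_harmonized_db(path)
    assert len(back) == 0 and list(back.columns) == TABLE1_COLUMNS


def test_harmonized_db_missing_climate_column_is_schema_error(tmp_path):
    import sqlite3

    df = _harmonized_frame(5).drop(columns=["tas_200"])
    path = tmp_path / "broken.sqlite"
    with sqlite3.connect(path) as con:
        df.to_sql("simulations", con, index=False)
    with pytest.raises(SchemaError, match="tas_200"):
        read_harmonized_db(path)


def test_harmonized_db_rejects_negative_precipitation(tmp_path):
    df = _harmonized_frame(5)
    df.loc[2, "prec_100"] = -1.0
    with pytest.raises(ValueError, match="prec"):
        write_harmonized_db(df, "rcp45_GCM-B", tmp_path / "db.sqlite")
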