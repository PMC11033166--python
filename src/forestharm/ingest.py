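"""Reading, validating and storing contributions and harmonized databases.

Contributors deliver two comma-separated UTF-8 files: a *simulation* file in
long form — per simulation-year one stand row (height statistics, LAI,
annual temperature and precipitation) plus one row per species holding its
basal-area share — and a *metadata* file with one row per simulation
(location, scenario family and hints, soil descriptors, management, model).

Harmonized output is SQLite, one database per climate scenario, each with a
``simulations`` table whose columns follow the published schema: identity
(SourceID, SimulationID, Year), the discrete ``vegetation_state`` string,
``dominant_height``, LAI, the soil vector, the Scenario label, and the
4 × 365 daily climate columns ``tas_1``..``vpd_365``.
"""

from __future__ import annotations

import math
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationRecord",
    "SimulationMetadata",
    "ValidationReport",
    "ValidationCheck",
    "SchemaError",
    "RowParseError",
    "TABLE1_COLUMNS",
    "CLIMATE_COLUMNS",
    "read_contribution",
    "validate_contribution",
    "write_harmonized_db",
    "read_harmonized_db",
    "write_metadata_db",
]

SIM_REQUIRED = [
    "source_id",
    "simulation_id",
    "year",
    "species",
    "share",
    "lai",
    "annual_temperature",
    "annual_precipitation",
]
SIM_HEIGHTS = ["height_min", "height_mean", "height_max"]
META_REQUIRED = [
    "source_id",
    "simulation_id",
    "latitude",
    "longitude",
    "trajectory_family",
    "management",
    "model_name",
    "model_level",
]
META_OPTIONAL = [
    "rcp_hint",
    "gcm_hint",
    "whc",
    "sand",
    "silt",
    "clay",
    "depth",
    "available_n",
    "water_rating",
    "fertility_rating",
]

CLIMATE_COLUMNS = [f"{v}_{d}" for v in ("tas", "prec", "rad", "vpd") for d in range(1, 366)]
TABLE1_COLUMNS = [
    "SourceID",
    "SimulationID",
    "Year",
    "vegetation_state",
    "dominant_height",
    "LAI",
    "WHC",
    "TextureSand",
    "TextureSilt",
    "TextureClay",
    "SoilDepth",
    "AvailableNitrogen",
    "Scenario",
] + CLIMATE_COLUMNS

DB_TABLE = "simulations"


class SchemaError(ValueError):
    """A file is missing a mandatory column or table."""


class RowParseError(ValueError):
    """A row holds an unparseable value; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass
class SimulationRecord:
    """One simulated stand-year."""

    source_id: str
    simulation_id: str
    year: int
    species_shares: dict[str, float]
    height_min: float | None
    height_mean: float | None
    height_max: float | None
    lai: float


@dataclass
class SimulationMetadata:
    """Per-simulation design and driver information."""

    source_id: str
    simulation_id: str
    latitude: float
    longitude: float
    trajectory_family: str
    rcp_hint: str | None
    gcm_hint: str | None
    annual_temperature: pd.Series  # °C by year
    annual_precipitation: pd.Series  # mm/yr by year
    management: str
    model_name: str
    model_level: str
    whc: float | None = None
    sand: float | None = None
    silt: float | None = None
    clay: float | None = None
    depth: float | None = None
    available_n: float | None = None
    water_rating: str | None = None
    fertility_rating: str | None = None


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    offending: list[str] = field(default_factory=list)
    message: str = ""


@dataclass
class ValidationReport:
    checks: list[ValidationCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]


def _numeric(df: pd.DataFrame, col: str) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        idx = int(np.nonzero(bad.to_numpy())[0][0])
        raise RowParseError(idx, f"column {col!r} value {raw.iloc[idx]!r} is not numeric")
    return out


def read_contribution(sim_path, meta_path) -> tuple[list[SimulationRecord], dict[str, SimulationMetadata]]:
    """Read and type one contribution (simulation + metadata CSV).

    Unknown columns are preserved in the parse but ignored. Missing mandatory
    columns raise :class:`SchemaError` naming the column; unparseable numeric
    cells raise :class:`RowParseError` with the row index.
    """
    sim = pd.read_csv(sim_path, dtype={"source_id": str, "simulation_id": str, "species": str})
    for col in SIM_REQUIRED:
        if col not in sim.columns:
            raise SchemaError(col)
    if not any(c in sim.columns for c in SIM_HEIGHTS):
        raise SchemaError("height_min/height_mean/height_max (at least one required)")
    meta = pd.read_csv(meta_path, dtype={"source_id": str, "simulation_id": str})
    for col in META_REQUIRED:
        if col not in meta.columns:
            raise SchemaError(col)

    for col in ["year", "share", "lai", "annual_temperature", "annual_precipitation"] + [
        c for c in SIM_HEIGHTS if c in sim.columns
    ]:
        sim[col] = _numeric(sim, col)
    for col in ["latitude", "longitude"] + [
        c for c in ("whc", "sand", "silt", "clay", "depth", "available_n") if c in meta.columns
    ]:
        meta[col] = _numeric(meta, col)

    is_stand = sim["species"].isna() | (sim["species"].astype(str).str.strip() == "")
    records: list[SimulationRecord] = []
    shares_by_key: dict[tuple[str, int], dict[str, float]] = {}
    for _, r in sim[~is_stand].iterrows():
        key = (str(r["simulation_id"]), int(r["year"]))
        shares_by_key.setdefault(key, {})[str(r["species"])] = float(r["share"])
    annual_by_sim: dict[str, list[tuple[int, float, float]]] = {}
    for _, r in sim[is_stand].iterrows():
        sim_id = str(r["simulation_id"])
        year = int(r["year"])

        def opt(col):
            if col not in sim.columns:
                return None
            v = r[col]
            return None if pd.isna(v) else float(v)

        records.append(
            SimulationRecord(
                source_id=str(r["source_id"]),
                simulation_id=sim_id,
                year=year,
                species_shares=shares_by_key.get((sim_id, year), {}),
                height_min=opt("height_min"),
                height_mean=opt("height_mean"),
                height_max=opt("height_max"),
                lai=float(r["lai"]) if not pd.isna(r["lai"]) else math.nan,
            )
        )
        annual_by_sim.setdefault(sim_id, []).append(
            (year, float(r["annual_temperature"]), float(r["annual_precipitation"]))
        )

    metadata: dict[str, SimulationMetadata] = {}
    for _, r in meta.iterrows():
        sim_id = str(r["simulation_id"])
        annual = sorted(annual_by_sim.get(sim_id, []))
        years = [a[0] for a in annual]

        def opt_meta(col, cast=float):
            if col not in meta.columns:
                return None
            v = r[col]
            if pd.isna(v) or (isinstance(v, str) and not v.strip()):
                return None
            return cast(v)

        sand, silt, clay = (opt_meta(c) for c in ("sand", "silt", "clay"))
        if sand is not None and silt is not None and clay is not None:
            if abs(sand + silt + clay - 100.0) > 1.0:
                raise RowParseError(
                    int(r.name), f"texture percentages sum to {sand + silt + clay}, expected 100 ± 1"
                )
        lat, lon = float(r["latitude"]), float(r["longitude"])
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise RowParseError(int(r.name), f"coordinates ({lat}, {lon}) out of range")
        metadata[sim_id] = SimulationMetadata(
            source_id=str(r["source_id"]),
            simulation_id=sim_id,
            latitude=lat,
            longitude=lon,
            trajectory_family=str(r["trajectory_family"]),
            rcp_hint=opt_meta("rcp_hint", str),
            gcm_hint=opt_meta("gcm_hint", str),
            annual_temperature=pd.Series([a[1] for a in annual], index=years, dtype=float),
            annual_precipitation=pd.Series([a[2] for a in annual], index=years, dtype=float),
            management=str(r["management"]),
            model_name=str(r["model_name"]),
            model_level=str(r["model_level"]),
            whc=opt_meta("whc"),
            sand=sand,
            silt=silt,
            clay=clay,
            depth=opt_meta("depth"),
            available_n=opt_meta("available_n"),
            water_rating=opt_meta("water_rating", str),
            fertility_rating=opt_meta("fertility_rating", str),
        )
    return records, metadata


def _species_level(name: str) -> bool:
    parts = name.strip().split()
    return len(parts) >= 2 and all(len(p) >= 2 for p in parts[:2])


def validate_contribution(
    records: list[SimulationRecord], metadata: dict[str, SimulationMetadata]
) -> ValidationReport:
    """Run the contribution checks; failures are reported, never raised.

    Checks: (a) one-to-one match of simulation ids between the two files,
    (b) gap-free annual year sequences, (c) presence of the three required
    indicators (species shares, at least one height statistic, LAI), and
    (d) species-level output (no plant-functional-type labels).
    """
    rec_ids = {r.simulation_id for r in records}
    meta_ids = set(metadata)
    mismatched = sorted((rec_ids - meta_ids) | (meta_ids - rec_ids))
    checks = [
        ValidationCheck(
            "id_match",
            not mismatched,
            mismatched,
            "simulation ids present in only one of the two files" if mismatched else "",
        )
    ]

    gap_ids = []
    by_sim: dict[str, list[int]] = {}
    for r in records:
        by_sim.setdefault(r.simulation_id, []).append(r.year)
    for sim_id, years in by_sim.items():
        ys = sorted(years)
        if len(set(ys)) != len(ys) or ys != list(range(ys[0], ys[-1] + 1)):
            gap_ids.append(sim_id)
    checks.append(
        ValidationCheck(
            "annual_continuity",
            not gap_ids,
            sorted(gap_ids),
            "years must be consecutive without gaps or duplicates" if gap_ids else "",
        )
    )

    missing_ind = []
    for sim_id in sorted(by_sim):
        recs = [r for r in records if r.simulation_id == sim_id]
        has_shares = any(r.species_shares for r in recs)
        has_height = any(
            v is not None for r in recs for v in (r.height_min, r.height_mean, r.height_max)
        )
        has_lai = all(math.isfinite(r.lai) for r in recs)
        if not (has_shares and has_height and has_lai):
            missing_ind.append(sim_id)
    checks.append(
        ValidationCheck(
            "required_indicators",
            not missing_ind,
            missing_ind,
            "species shares, at least one height statistic and LAI are required"
            if missing_ind
            else "",
        )
    )

    pft_ids = sorted(
        {
            r.simulation_id
            for r in records
            for sp in r.species_shares
            if not _species_level(sp)
        }
    )
    checks.append(
        ValidationCheck(
            "species_level",
            not pft_ids,
            pft_ids,
            "output must be at tree-species level (Genus epithet), not functional types"
            if pft_ids
            else "",
        )
    )
    return ValidationReport(checks=checks)


def _validate_harmonized(rows: pd.DataFrame) -> None:
    missing = [c for c in TABLE1_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(missing[0])
    if len(rows):
        clim = rows[CLIMATE_COLUMNS]
        if clim.isna().any().any():
            raise ValueError("harmonized rows contain missing daily climate values")
        prec = rows[[c for c in CLIMATE_COLUMNS if c.startswith("prec_")]]
        vpd = rows[[c for c in CLIMATE_COLUMNS if c.startswith("vpd_")]]
        if (prec.to_numpy() < 0).any() or (vpd.to_numpy() < 0).any():
            raise ValueError("daily precipitation and vpd must be >= 0")


def write_harmonized_db(rows: pd.DataFrame, scenario: str, path) -> None:
    """Write one scenario's harmonized rows to a SQLite database.

    All rows must carry the given scenario label; the table keeps the full
    published column set even when empty.
    """
    if len(rows):
        scenarios = set(rows["Scenario"].unique())
        if scenarios != {scenario}:
            raise ValueError(f"rows carry scenarios {sorted(scenarios)}, expected only {scenario!r}")
    _validate_harmonized(rows)
    out = rows[TABLE1_COLUMNS] if len(rows) else pd.DataFrame(columns=TABLE1_COLUMNS)
    with sqlite3.connect(path) as con:
        out.to_sql(DB_TABLE, con, if_exists="replace", index=False)


def read_harmonized_db(path) -> pd.DataFrame:
    """Read a harmonized scenario database back into a data frame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with sqlite3.connect(path) as con:
        tables = pd.read_sql(
            "SELECT name FROM sqlite_master WHERE type='table'", con
        )["name"].tolist()
        if DB_TABLE not in tables:
            raise SchemaError(DB_TABLE)
        df = pd.read_sql(f"SELECT * FROM {DB_TABLE}", con)
    missing = [c for c in TABLE1_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing[0])
    return df


def write_metadata_db(metadata: dict[str, SimulationMetadata], soil_vectors: dict, path) -> None:
    """Write the cross-scenario metadata database (locations + soil vectors)."""
    rows = []
    for sim_id, m in metadata.items():
        sv = soil_vectors.get(sim_id)
        rows.append(
            {
                "SourceID": m.source_id,
                "SimulationID": sim_id,
                "Latitude": m.latitude,
                "Longitude": m.longitude,
                "TrajectoryFamily": m.trajectory_family,
                "Management": m.management,
                "ModelName": m.model_name,
                "ModelLevel": m.model_level,
                "WHC": sv.whc if sv else None,
                "TextureSand": sv.sand if sv else None,
                "TextureSilt": sv.silt if sv else None,
                "TextureClay": sv.clay if sv else None,
                "SoilDepth": sv.depth if sv else None,
                "AvailableNitrogen": sv.available_n if sv else None,
            }
        )
    with sqlite3.connect(path) as con:
        pd.DataFrame(rows).to_sql("metadata", con, if_exists="replace", index=False)
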