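"""Synthetic scenario catalogues, simulation sets, soil grids and height tables.

Every downstream harmonization stage is testable against known ground truth:
the weather generator produces daily trajectories with prescribed warming
and precipitation trends, simulated contributions are derived from one known
trajectory through a known temperature offset and precipitation factor, soil
grids are built so the pseudo-mineralization GLM is the true data-generating
model, and height-calibration tables follow known per-species linear
relations.

Daily weather is deliberately minimal: a sinusoidal seasonal temperature
cycle with AR(1) day-to-day noise, Bernoulli–Gamma precipitation, a
clear-sky radiation curve damped on wet days, and VPD derived from the
saturation vapour pressure at the daily temperature. Years have exactly
365 days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import lfilter

from . import soil as _soil

__all__ = [
    "DAYS_PER_YEAR",
    "GridSpec",
    "GridCell",
    "ClimateTrajectory",
    "ScenarioCatalogue",
    "HeightProfile",
    "SimTruth",
    "SyntheticTruth",
    "RateCoefficients",
    "default_trend_spec",
    "gen_scenario_catalogue",
    "gen_simulation_set",
    "gen_soil_grids",
    "gen_height_calibration",
    "default_height_truth",
    "DEFAULT_PROFILES",
]

DAYS_PER_YEAR = 365
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_OF_DAY = np.repeat(np.arange(12), MONTH_LENGTHS)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lat/lon grid extent with square cells (degrees)."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.11

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("grid extent is empty")

    def cells(self) -> list["GridCell"]:
        lats = np.arange(self.lat_min + self.resolution / 2, self.lat_max, self.resolution)
        lons = np.arange(self.lon_min + self.resolution / 2, self.lon_max, self.resolution)
        out = []
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                out.append(GridCell(f"c{i:03d}_{j:03d}", float(la), float(lo), self.resolution))
        if not out:
            raise ValueError("grid extent produces no cells")
        return out


@dataclass(frozen=True)
class GridCell:
    cell_id: str
    lat: float
    lon: float
    size: float


@dataclass
class ClimateTrajectory:
    """One scenario × grid-cell daily climate series.

    Daily arrays have shape ``(n_years, 365)``; annual summaries (MAT °C,
    ANP mm) are derived on demand.
    """

    scenario_id: str
    cell_id: str
    lat: float
    lon: float
    years: np.ndarray
    tas: np.ndarray
    prec: np.ndarray
    rad: np.ndarray
    vpd: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.years)
        for name in ("tas", "prec", "rad", "vpd"):
            arr = getattr(self, name)
            if arr.shape != (n, DAYS_PER_YEAR):
                raise ValueError(f"{name} must have shape ({n}, {DAYS_PER_YEAR}), got {arr.shape}")
        if np.any(self.prec < 0):
            raise ValueError("precipitation must be >= 0")
        if np.any(self.vpd < 0):
            raise ValueError("vpd must be >= 0")

    @property
    def annual_mat(self) -> np.ndarray:
        return self.tas.mean(axis=1)

    @property
    def annual_anp(self) -> np.ndarray:
        return self.prec.sum(axis=1)

    def monthly_mean_temperature(self, year: int) -> np.ndarray:
        row = self.tas[self.year_index(year)]
        return np.array([row[MONTH_OF_DAY == m].mean() for m in range(12)])

    def year_index(self, year: int) -> int:
        idx = np.nonzero(self.years == year)[0]
        if len(idx) == 0:
            raise KeyError(f"year {year} not in trajectory period")
        return int(idx[0])

    def replace(self, **kwargs) -> "ClimateTrajectory":
        return _dc_replace(self, **kwargs)


@dataclass
class ScenarioCatalogue:
    """All trajectories of a scenario set, keyed by (scenario_id, cell_id)."""

    trajectories: dict[tuple[str, str], ClimateTrajectory]
    cells: list[GridCell]
    period: tuple[int, int]

    @property
    def scenario_ids(self) -> list[str]:
        return sorted({sid for sid, _ in self.trajectories})

    def nearest_cell(self, lat: float, lon: float) -> GridCell:
        from .climate import great_circle_km

        return min(self.cells, key=lambda c: great_circle_km(lat, lon, c.lat, c.lon))

    def to_parquet(self, path) -> None:
        """Serialize to a single columnar file (one row per trajectory-year)."""
        trajs = self._ordered()
        day_cols = {
            f"{v}_{d}": np.concatenate([getattr(t, v)[:, d - 1] for t in trajs])
            for v in ("tas", "prec", "rad", "vpd")
            for d in range(1, DAYS_PER_YEAR + 1)
        }
        meta = {
            "scenario_id": np.concatenate([[t.scenario_id] * len(t.years) for t in trajs]),
            "cell_id": np.concatenate([[t.cell_id] * len(t.years) for t in trajs]),
            "lat": np.concatenate([[t.lat] * len(t.years) for t in trajs]),
            "lon": np.concatenate([[t.lon] * len(t.years) for t in trajs]),
            "cell_size": np.concatenate([[self.cells[0].size] * len(t.years) for t in trajs]),
            "year": np.concatenate([t.years for t in trajs]),
        }
        pd.DataFrame({**meta, **day_cols}).to_parquet(path, index=False)

    def _ordered(self) -> list[ClimateTrajectory]:
        return [self.trajectories[k] for k in sorted(self.trajectories)]

    @classmethod
    def from_parquet(cls, path) -> "ScenarioCatalogue":
        df = pd.read_parquet(path)
        trajectories: dict[tuple[str, str], ClimateTrajectory] = {}
        cells: dict[str, GridCell] = {}
        for (sid, cid), g in df.groupby(["scenario_id", "cell_id"], sort=True):
            g = g.sort_values("year")
            arrays = {
                v: g[[f"{v}_{d}" for d in range(1, DAYS_PER_YEAR + 1)]].to_numpy(dtype=float)
                for v in ("tas", "prec", "rad", "vpd")
            }
            lat, lon = float(g["lat"].iloc[0]), float(g["lon"].iloc[0])
            trajectories[(sid, cid)] = ClimateTrajectory(
                scenario_id=sid, cell_id=cid, lat=lat, lon=lon,
                years=g["year"].to_numpy(dtype=int), **arrays,
            )
            cells.setdefault(cid, GridCell(cid, lat, lon, float(g["cell_size"].iloc[0])))
        years = df["year"].to_numpy()
        return cls(
            trajectories=trajectories,
            cells=[cells[k] for k in sorted(cells)],
            period=(int(years.min()), int(years.max())),
        )


def default_trend_spec(gcms: list[str], rcps: list[str]) -> dict[str, tuple[float, float]]:
    """Per-scenario (T slope °C/yr, relative P slope fraction/yr) defaults.

    GCM modifiers are spaced widely (±0.025 °C/yr, ∓0.003 fraction/yr) so the
    members of one RCP are separated by several standard errors of a realized
    30-year trend at the generator's interannual variability — the premise of
    trajectory-recovery testing.
    """
    base_t = {"historical": 0.015, "rcp26": 0.010, "rcp45": 0.030, "rcp85": 0.050}
    base_p = {"historical": 0.0, "rcp26": 0.0005, "rcp45": -0.0005, "rcp85": -0.0015}
    spec = {}
    for family in ["historical"] + list(rcps):
        for k, gcm in enumerate(gcms):
            mod = k - (len(gcms) - 1) / 2.0
            t = base_t.get(family, 0.02) + 0.025 * mod
            p = base_p.get(family, 0.0) - 0.003 * mod
            spec[f"{family}_{gcm}"] = (t, p)
    return spec


def _simulate_year(rng, lat, mat_year, anp_year):
    """One 365-day year of tas/prec/rad/vpd around given annual MAT and ANP."""
    doy = np.arange(DAYS_PER_YEAR)
    phase = 2 * math.pi * (doy - 15) / DAYS_PER_YEAR
    amplitude = 6.0 + 0.25 * max(lat - 35.0, 0.0)
    seasonal = -amplitude * np.cos(phase)
    ar_noise = lfilter([1.0], [1.0, -0.75], rng.normal(0.0, 1.6, DAYS_PER_YEAR))
    tas = mat_year + seasonal + ar_noise - ar_noise.mean()

    wet_prob = 0.35 + 0.08 * np.cos(phase)  # slightly wetter winters
    wet = rng.random(DAYS_PER_YEAR) < wet_prob
    shape = 0.7
    mean_intensity = anp_year / max(wet.sum(), 1) / shape
    prec = np.zeros(DAYS_PER_YEAR)
    prec[wet] = rng.gamma(shape, mean_intensity, wet.sum())
    if prec.sum() > 0:
        prec *= anp_year / prec.sum()  # pin the annual sum to the prescribed ANP

    clear_sky = np.maximum(30.0, 210.0 - 170.0 * np.cos(phase))
    clear_sky *= max(0.5, 1.0 - 0.012 * max(lat - 40.0, 0.0))
    rad = clear_sky * np.where(wet, 0.55, 1.0) * (1 + rng.normal(0, 0.05, DAYS_PER_YEAR))
    rad = np.maximum(rad, 0.0)

    es = 0.6108 * np.exp(17.27 * tas / (tas + 237.3))  # kPa, Magnus form
    rh = np.where(wet, 0.85, 0.62) + rng.normal(0, 0.04, DAYS_PER_YEAR)
    vpd = np.maximum(es * (1.0 - np.clip(rh, 0.2, 1.0)), 0.0)
    return tas, prec, rad, vpd


def _simulate_trajectory(rng, scenario_id, cell, years, base_mat, base_anp, t_slope, p_slope):
    n = len(years)
    tas = np.empty((n, DAYS_PER_YEAR))
    prec = np.empty((n, DAYS_PER_YEAR))
    rad = np.empty((n, DAYS_PER_YEAR))
    vpd = np.empty((n, DAYS_PER_YEAR))
    for i, year in enumerate(years):
        t_off = t_slope * (year - years[0]) + rng.normal(0.0, 0.25)
        p_fac = max(0.2, 1.0 + p_slope * (year - years[0])) * math.exp(rng.normal(0.0, 0.04))
        tas[i], prec[i], rad[i], vpd[i] = _simulate_year(
            rng, cell.lat, base_mat + t_off, base_anp * p_fac
        )
    return ClimateTrajectory(
        scenario_id=scenario_id, cell_id=cell.cell_id, lat=cell.lat, lon=cell.lon,
        years=np.asarray(years, dtype=int), tas=tas, prec=prec, rad=rad, vpd=vpd,
    )


def gen_scenario_catalogue(
    n_gcm: int,
    rcp_list: list[str],
    years,
    grid_spec: GridSpec,
    trend_spec: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base_mat: float = 8.0,
    base_anp: float = 800.0,
) -> ScenarioCatalogue:
    """Generate the full scenario catalogue: (historical + RCPs) × GCMs × cells.

    ``years`` is an inclusive, contiguous range of calendar years shared by
    all scenarios. Cell base climate follows a latitudinal temperature lapse
    and a longitudinal precipitation gradient; per-scenario trends come from
    ``trend_spec`` (scenario_id → (°C/yr, fraction/yr)).
    """
    years = np.asarray(list(years), dtype=int)
    if len(years) == 0:
        raise ValueError("year range is empty")
    gcms = [f"GCM-{chr(65 + i)}" for i in range(n_gcm)]
    families = ["historical"] + list(rcp_list)
    scenario_ids = [f"{f}_{g}" for f in families for g in gcms]
    trend_spec = trend_spec if trend_spec is not None else default_trend_spec(gcms, rcp_list)
    missing = [s for s in scenario_ids if s not in trend_spec]
    if missing:
        raise ValueError(f"trend_spec lacks scenarios {missing}")

    cells = grid_spec.cells()
    lat_mid = (grid_spec.lat_min + grid_spec.lat_max) / 2
    trajectories = {}
    for si, sid in enumerate(scenario_ids):
        t_slope, p_slope = trend_spec[sid]
        for ci, cell in enumerate(cells):
            rng = np.random.default_rng([seed, si, ci])
            cell_mat = base_mat - 0.65 * (cell.lat - lat_mid)
            cell_anp = base_anp * (1 + 0.1 * math.sin(cell.lon))
            trajectories[(sid, cell.cell_id)] = _simulate_trajectory(
                rng, sid, cell, years, cell_mat, cell_anp, t_slope, p_slope
            )
    return ScenarioCatalogue(
        trajectories=trajectories, cells=cells, period=(int(years[0]), int(years[-1]))
    )


# ---------------------------------------------------------------------------
# simulation sets


@dataclass(frozen=True)
class HeightProfile:
    """Height-reporting convention of one simulated 'model'."""

    name: str
    reports: frozenset[str]  # subset of {"min", "mean", "max"}

    def __post_init__(self) -> None:
        if not self.reports:
            raise ValueError(f"profile {self.name!r} reports no height statistic")
        bad = self.reports - {"min", "mean", "max"}
        if bad:
            raise ValueError(f"profile {self.name!r} reports unknown statistics {sorted(bad)}")


DEFAULT_PROFILES = (
    HeightProfile("daily-full", frozenset({"min", "mean", "max"})),
    HeightProfile("mean-only", frozenset({"mean"})),
    HeightProfile("minmax-only", frozenset({"min", "max"})),
)


@dataclass
class SimTruth:
    scenario_id: str
    cell_id: str
    temperature_offset: float
    precipitation_factor: float
    annual: pd.DataFrame  # year, lai, dominant_height
    shares: pd.DataFrame  # year, species, share


@dataclass
class SyntheticTruth:
    """Ground truth of a generated artifact, keyed by entity id."""

    simulations: dict[str, SimTruth] = field(default_factory=dict)
    glm_coefficients: "RateCoefficients | None" = None
    rate_true: np.ndarray | None = None
    available_n_true: np.ndarray | None = None
    height_coefficients: dict | None = None


@dataclass(frozen=True)
class SimNoise:
    """Noise levels linking a simulation to its source trajectory."""

    offset_sd: float = 0.7  # °C, spread of the true additive offset
    log_factor_sd: float = 0.10  # spread of log precipitation factor
    temperature_sd: float = 0.05  # °C, annual metadata noise
    precipitation_cv: float = 0.01  # relative annual metadata noise


def _simplex_walk(rng, n_species: int, n_years: int, step: float = 0.02) -> np.ndarray:
    """Bounded random walk on the simplex (succession-like share dynamics).

    Returns shares of shape (n_years, n_species); an implicit remainder
    component keeps each year's sum strictly <= 1.
    """
    x = rng.dirichlet(np.ones(n_species + 1) * 3.0)
    out = np.empty((n_years, n_species))
    for t in range(n_years):
        out[t] = x[:-1]
        x = np.maximum(x + rng.normal(0.0, step, n_species + 1), 1e-3)
        x /= x.sum()
    return out


def gen_simulation_set(
    catalogue: ScenarioCatalogue,
    n_sims: int,
    species_pool: list[str],
    profiles=DEFAULT_PROFILES,
    seed: int = 0,
    noise: SimNoise = SimNoise(),
    source_id: str = "synth",
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate contributor-style simulation and metadata tables.

    Each simulation is tied to exactly one catalogue trajectory: its annual
    temperature series is the trajectory's MAT plus a true offset (plus
    bounded metadata noise) and its annual precipitation the trajectory's ANP
    times a true factor. The simulation file is in long form — one stand row
    per year (heights, LAI, annual climate) plus one row per species-year
    share. Returns (simulation table, metadata table, truth).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not species_pool:
        raise ValueError("species pool is empty")
    profiles = list(profiles)
    for p in profiles:
        if not p.reports:
            raise ValueError(f"profile {p.name} reports nothing")

    scenario_ids = catalogue.scenario_ids
    sim_rows: list[dict] = []
    meta_rows: list[dict] = []
    truth = SyntheticTruth()
    y0, y1 = catalogue.period
    years = np.arange(y0, y1 + 1)
    n_years = len(years)

    for i in range(n_sims):
        rng = np.random.default_rng([seed, 1_000 + i])
        sim_id = f"sim{i:04d}"
        sid = scenario_ids[rng.integers(0, len(scenario_ids))]
        cell = catalogue.cells[rng.integers(0, len(catalogue.cells))]
        traj = catalogue.trajectories[(sid, cell.cell_id)]
        profile = profiles[rng.integers(0, len(profiles))]

        delta = rng.normal(0.0, noise.offset_sd)
        factor = math.exp(rng.normal(0.0, noise.log_factor_sd))
        t_noise = rng.normal(0.0, noise.temperature_sd, n_years) if noise.temperature_sd > 0 else 0.0
        p_noise = (
            np.exp(rng.normal(0.0, noise.precipitation_cv, n_years))
            if noise.precipitation_cv > 0
            else 1.0
        )
        annual_t = traj.annual_mat + delta + t_noise
        annual_p = traj.annual_anp * factor * p_noise

        n_sp = int(rng.integers(1, min(3, len(species_pool)) + 1))
        species = list(rng.choice(np.asarray(species_pool, dtype=object), n_sp, replace=False))
        shares = _simplex_walk(rng, n_sp, n_years)

        h_max_asym = rng.uniform(24.0, 36.0)
        age0 = rng.uniform(5.0, 40.0)
        lai_asym = rng.uniform(3.0, 6.0)
        annual_records = []
        share_records = []
        for t, year in enumerate(years):
            dom_h = h_max_asym * (1.0 - math.exp(-0.045 * (age0 + t)))
            top_h = dom_h / 0.95
            mean_h = top_h / 1.18
            min_h = mean_h * 0.72
            lai = max(lai_asym * (1.0 - math.exp(-0.08 * (age0 / 2 + t))) + rng.normal(0, 0.1), 0.0)
            row = {
                "source_id": source_id,
                "simulation_id": sim_id,
                "year": int(year),
                "species": "",
                "share": np.nan,
                "height_min": min_h if "min" in profile.reports else np.nan,
                "height_mean": mean_h if "mean" in profile.reports else np.nan,
                "height_max": top_h if "max" in profile.reports else np.nan,
                "lai": lai,
                "annual_temperature": float(annual_t[t]),
                "annual_precipitation": float(annual_p[t]),
            }
            sim_rows.append(row)
            annual_records.append({"year": int(year), "lai": lai, "dominant_height": dom_h})
            for k, sp in enumerate(species):
                share = float(shares[t, k])
                sim_rows.append(
                    {
                        "source_id": source_id,
                        "simulation_id": sim_id,
                        "year": int(year),
                        "species": sp,
                        "share": share,
                        "height_min": np.nan,
                        "height_mean": np.nan,
                        "height_max": np.nan,
                        "lai": np.nan,
                        "annual_temperature": np.nan,
                        "annual_precipitation": np.nan,
                    }
                )
                share_records.append({"year": int(year), "species": sp, "share": share})

        family = "baseline" if sid.startswith("historical") else "RCP"
        rcp_hint = None if family == "baseline" else sid.split("_")[0]
        soil_mode = rng.random()
        meta = {
            "source_id": source_id,
            "simulation_id": sim_id,
            "latitude": cell.lat + rng.uniform(-cell.size / 2, cell.size / 2),
            "longitude": cell.lon + rng.uniform(-cell.size / 2, cell.size / 2),
            "trajectory_family": family,
            "rcp_hint": rcp_hint,
            "gcm_hint": None,
            "management": "none" if rng.random() < 0.5 else "business-as-usual",
            "model_name": profile.name,
            "model_level": "stand",
            "whc": np.nan,
            "sand": np.nan,
            "silt": np.nan,
            "clay": np.nan,
            "depth": np.nan,
            "available_n": np.nan,
            "water_rating": None,
            "fertility_rating": None,
        }
        if soil_mode < 0.4:  # full numeric soil description
            tex = rng.dirichlet([3.0, 3.0, 2.0]) * 100.0
            meta.update(
                whc=rng.uniform(60.0, 200.0),
                sand=tex[0],
                silt=tex[1],
                clay=tex[2],
                depth=rng.uniform(300.0, 1500.0),
                available_n=rng.uniform(25.0, 110.0),
            )
        elif soil_mode < 0.7:  # descriptive ratings only
            meta.update(
                water_rating=str(rng.choice(list(_soil.DEFAULT_WATER_RATING))),
                fertility_rating=str(rng.choice(list(_soil.DEFAULT_FERTILITY_RATING))),
            )
        # else: everything filled from the grids
        meta_rows.append(meta)

        truth.simulations[sim_id] = SimTruth(
            scenario_id=sid,
            cell_id=cell.cell_id,
            temperature_offset=delta,
            precipitation_factor=factor,
            annual=pd.DataFrame(annual_records),
            shares=pd.DataFrame(share_records),
        )

    return pd.DataFrame(sim_rows), pd.DataFrame(meta_rows), truth


# ---------------------------------------------------------------------------
# soil grids


@dataclass(frozen=True)
class RateCoefficients:
    """True Gamma/log GLM coefficients of the pseudo-mineralization rate."""

    const: float = -6.45
    mat: float = 0.09  # per °C
    anp: float = 0.0005  # per mm
    seasonality: float = -0.0005
    ph: float = 0.15

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "const": self.const,
                "mat": self.mat,
                "anp": self.anp,
                "seasonality": self.seasonality,
                "ph": self.ph,
            }
        )

    def rate(self, mat, anp, seasonality, ph):
        eta = (
            self.const
            + self.mat * np.asarray(mat)
            + self.anp * np.asarray(anp)
            + self.seasonality * np.asarray(seasonality)
            + self.ph * np.asarray(ph)
        )
        return np.exp(eta)


LAYER_BOUNDS = [(0.0, 0.05), (0.05, 0.15), (0.15, 0.30)]


def gen_soil_grids(
    extent: GridSpec,
    glm_truth: RateCoefficients | None = None,
    seed: int = 0,
    class_noise_sd: float = 0.15,
) -> tuple[xr.Dataset, SyntheticTruth]:
    """Generate a soil/climate grid stack with the rate GLM as true model.

    Each cell carries an SQ1-style fertility class, per-layer nitrogen
    content and bulk density (0–30 cm in three layers), pH, WHC, texture,
    depth and the climate covariates of the rate model. The true
    pseudo-mineralization rate is the GLM inverse link applied to the cell's
    covariates; the fertility class is the reclassification value nearest to
    the true available N after multiplicative lognormal jitter
    (``class_noise_sd``), emulating classification error of a fertility map.
    """
    glm_truth = glm_truth or RateCoefficients()
    coeffs = glm_truth.as_series().to_numpy()
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("GLM truth coefficients must be finite")
    cells = extent.cells()
    lats = sorted({c.lat for c in cells})
    lons = sorted({c.lon for c in cells})
    rng = np.random.default_rng([seed, 77])
    shape = (len(lats), len(lons))

    lat_arr = np.asarray(lats)[:, None]
    lon_arr = np.asarray(lons)[None, :]
    mat = 11.0 - 0.8 * (lat_arr - min(lats)) + rng.normal(0, 1.2, shape)
    anp = np.clip(650.0 + 150.0 * np.sin(lon_arr) + 20.0 * (lat_arr - min(lats)) + rng.normal(0, 80, shape), 300, None)
    seasonality = np.clip(420.0 + 35.0 * (lat_arr - min(lats)) + rng.normal(0, 40, shape), 100, None)
    ph = np.clip(5.6 + rng.normal(0, 0.8, shape), 3.8, 8.0)

    texture = rng.dirichlet([3.0, 3.0, 2.0], size=shape) * 100.0
    sand, silt, clay = texture[..., 0], texture[..., 1], texture[..., 2]
    depth = rng.uniform(300.0, 1500.0, shape)
    whc = np.clip(0.12 * depth * (silt + clay) / 100.0 + rng.normal(0, 15, shape), 20.0, 260.0)

    n_layers = len(LAYER_BOUNDS)
    n_content = np.clip(
        np.stack([rng.uniform(1.8, 3.2, shape) * f for f in (1.0, 0.8, 0.6)]), 0.2, None
    )
    bulk_density = rng.uniform(1100.0, 1500.0, (n_layers,) + shape)

    thickness = np.array([b - a for a, b in LAYER_BOUNDS])[:, None, None]
    pool = (n_content * bulk_density * thickness / 1000.0).sum(axis=0) * 10_000.0  # kg/ha

    rate_true = glm_truth.rate(mat, anp, seasonality, ph)
    available_n_true = rate_true * pool

    reclass = _soil.DEFAULT_FERTILITY_RECLASS
    class_values = np.array([reclass[c] for c in sorted(reclass)])
    jittered = available_n_true * np.exp(rng.normal(0.0, class_noise_sd, shape))
    sq1 = np.array(sorted(reclass))[
        np.abs(np.log(jittered[..., None]) - np.log(class_values[None, None, :])).argmin(axis=-1)
    ]

    ds = xr.Dataset(
        {
            "sq1": (("lat", "lon"), sq1.astype(int)),
            "mat": (("lat", "lon"), mat),
            "anp": (("lat", "lon"), anp),
            "seasonality": (("lat", "lon"), seasonality),
            "ph": (("lat", "lon"), ph),
            "sand": (("lat", "lon"), sand),
            "silt": (("lat", "lon"), silt),
            "clay": (("lat", "lon"), clay),
            "depth": (("lat", "lon"), depth),
            "whc": (("lat", "lon"), whc),
            "n_content": (("layer", "lat", "lon"), n_content),
            "bulk_density": (("layer", "lat", "lon"), bulk_density),
            "layer_top": (("layer",), np.array([a for a, _ in LAYER_BOUNDS])),
            "layer_bottom": (("layer",), np.array([b for _, b in LAYER_BOUNDS])),
            "available_n_true": (("lat", "lon"), available_n_true),
            "rate_true": (("lat", "lon"), rate_true),
        },
        coords={"lat": lats, "lon": lons, "layer": np.arange(n_layers)},
        attrs={"resolution": extent.resolution},
    )
    truth = SyntheticTruth(
        glm_coefficients=glm_truth, rate_true=rate_true, available_n_true=available_n_true
    )
    return ds, truth


# ---------------------------------------------------------------------------
# height calibration tables


def default_height_truth(species_list: list[str], seed: int = 0) -> dict[str, dict[str, float]]:
    """Per-species true linear height relations.

    ``dom_mean``/``dom_max`` give dominant = dom_mean·mean + dom_max·max;
    ``max_intercept``/``max_slope`` give the species' max ~ mean line.
    """
    rng = np.random.default_rng([seed, 4242])
    truth = {}
    for sp in species_list:
        z = rng.normal(0.0, 1.0, 3)
        truth[sp] = {
            "dom_mean": 0.28 + 0.03 * z[0],
            "dom_max": 0.68 - 0.02 * z[0],
            "max_intercept": 0.4 + 0.15 * abs(z[1]),
            "max_slope": 1.12 + 0.04 * z[2],
        }
    return truth


def gen_height_calibration(
    n_stands: int,
    species_list: list[str],
    coeff_truth: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    structure_sd: float = 1.0,
) -> pd.DataFrame:
    """Generate a (species, min, mean, max, dominant) calibration table.

    ``n_stands`` rows are drawn per species. ``structure_sd`` (m) is the
    stand-to-stand spread of maximum height around the species' max ~ mean
    line — without it mean and max are exactly collinear and the
    dominant-height coefficients are unidentifiable — while ``noise_sd`` (m)
    is observation noise on the dominant height itself. With both at zero the
    table is exactly linear per species.
    """
    if n_stands < 2:
        raise ValueError("need at least 2 stands per species")
    if noise_sd < 0 or structure_sd < 0:
        raise ValueError("noise levels must be >= 0")
    coeff_truth = coeff_truth or default_height_truth(species_list, seed=seed)
    rng = np.random.default_rng([seed, 515])
    rows = []
    for sp in species_list:
        c = coeff_truth[sp]
        mean = rng.uniform(8.0, 35.0, n_stands)
        spread = rng.normal(0.0, structure_sd, n_stands) if structure_sd > 0 else 0.0
        mx = np.maximum(c["max_intercept"] + c["max_slope"] * mean + spread, mean)
        dom = c["dom_mean"] * mean + c["dom_max"] * mx
        if noise_sd > 0:
            dom = dom + rng.normal(0.0, noise_sd, n_stands)
        mn = np.clip(mean - (mx - mean) * rng.uniform(0.6, 1.3, n_stands), 0.5, mean)
        for j in range(n_stands):
            rows.append(
                {
                    "species": sp,
                    "height_min": float(mn[j]),
                    "height_mean": float(mean[j]),
                    "height_max": float(mx[j]),
                    "dominant_height": float(dom[j]),
                }
            )
    return pd.DataFrame(rows)
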