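"""Matching simulations to daily climate trajectories.

Contributed simulations carry only annual temperature and precipitation
summaries; the harmonized database instead stores full daily series taken
from a catalogue of scenario trajectories (historical + RCPs × GCMs on a
0.11° grid). Matching proceeds in three steps:

1. *trajectory selection* — candidate trajectories at the nearest grid cell
   (restricted by the metadata's scenario family and any RCP/GCM hints) are
   scored by the difference in warming/precipitation trends,
   ΔT + 0.1·ΔP with ΔT in °C per century and ΔP in percent precipitation
   change per century, and the smallest difference wins;
2. *level adjustment* — an additive temperature offset and a multiplicative
   precipitation factor shift the chosen trajectory to the simulation's mean
   temperature and precipitation level;
3. *year matching* — each simulation year is paired with one of its three
   best-matching scenario years (index |ΔT| + 0.1·|ΔP%|, sampled uniformly
   with replacement), and that year's daily values fill the 4 × 365 columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MATCH_WEIGHT",
    "MatchResult",
    "trend_slopes",
    "trajectory_distance",
    "candidate_scenarios",
    "select_trajectory",
    "adjust_trajectory",
    "year_distance",
    "match_years",
    "assemble_daily",
    "great_circle_km",
]

#: Weight of the precipitation term in both matching indices.
MATCH_WEIGHT = 0.1

YEARS_PER_CENTURY = 100.0


@dataclass
class MatchResult:
    """Outcome of matching one simulation to the catalogue."""

    scenario_id: str
    cell_id: str
    temperature_offset: float  # °C, additive
    precipitation_factor: float  # unitless, multiplicative
    year_mapping: dict[int, int]  # simulation year -> scenario year

    def __post_init__(self) -> None:
        if self.precipitation_factor <= 0:
            raise ValueError("precipitation factor must be > 0")


def trend_slopes(annual_t: pd.Series, annual_p: pd.Series) -> tuple[float, float]:
    """OLS warming and relative precipitation trends of annual series.

    ``annual_t`` (°C) and ``annual_p`` (mm/yr) are indexed by year. Returns
    the temperature slope in °C/yr and the precipitation slope as a fraction
    of the series mean per year.
    """
    if len(annual_t) < 3 or len(annual_p) < 3:
        raise ValueError("need at least 3 years to estimate trends")
    for s in (annual_t, annual_p):
        years = np.asarray(s.index, dtype=float)
        if np.ptp(years) == 0:
            raise ValueError("year vector is constant; slope undefined")
    slope_t = float(np.polyfit(np.asarray(annual_t.index, float), annual_t.to_numpy(float), 1)[0])
    p_vals = annual_p.to_numpy(float)
    p_mean = float(p_vals.mean())
    if p_mean <= 0:
        raise ValueError("mean annual precipitation must be > 0")
    slope_p = float(np.polyfit(np.asarray(annual_p.index, float), p_vals, 1)[0]) / p_mean
    return slope_t, slope_p


def trajectory_distance(
    sim_slopes: tuple[float, float],
    cand_slopes: tuple[float, float],
    weight: float = MATCH_WEIGHT,
) -> float:
    """Trend-difference index ΔT + 0.1·ΔP.

    ΔT is the absolute temperature-slope difference in °C per century; ΔP the
    absolute relative-precipitation-slope difference in percent per century.
    """
    for v in (*sim_slopes, *cand_slopes):
        if not math.isfinite(v):
            raise ValueError("slopes must be finite")
    dt = abs(sim_slopes[0] - cand_slopes[0]) * YEARS_PER_CENTURY
    dp = abs(sim_slopes[1] - cand_slopes[1]) * YEARS_PER_CENTURY * 100.0
    return dt + weight * dp


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance between two points in km."""
    r = 6371.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def candidate_scenarios(meta, catalogue) -> list[str]:
    """Scenario ids compatible with the metadata's trajectory family and hints.

    Baseline simulations match historical trajectories only; RCP simulations
    with an RCP hint match that RCP's members (optionally narrowed by a GCM
    hint); SRES or unhinted future simulations match all non-historical
    trajectories.
    """
    ids = catalogue.scenario_ids
    family = (meta.trajectory_family or "").lower()
    if family == "baseline":
        cands = [s for s in ids if s.startswith("historical")]
    else:
        cands = [s for s in ids if not s.startswith("historical")]
        rcp = getattr(meta, "rcp_hint", None)
        if rcp:
            cands = [s for s in cands if s.startswith(str(rcp).lower())]
        gcm = getattr(meta, "gcm_hint", None)
        if gcm:
            cands = [s for s in cands if s.endswith(str(gcm))]
    if not cands:
        raise ValueError(
            f"no catalogue scenario compatible with family={meta.trajectory_family!r}, "
            f"rcp_hint={getattr(meta, 'rcp_hint', None)!r}, gcm_hint={getattr(meta, 'gcm_hint', None)!r}"
        )
    return sorted(cands)


def _overlap_index(sim_years, traj) -> np.ndarray:
    """Indices of trajectory years overlapping the simulation period.

    Simulations indexed 1..N (rather than calendar years) overlap nowhere;
    the full trajectory period is used then.
    """
    mask = np.isin(traj.years, np.asarray(list(sim_years)))
    if mask.any():
        return np.nonzero(mask)[0]
    return np.arange(len(traj.years))


def select_trajectory(meta, catalogue, weight: float = MATCH_WEIGHT) -> str:
    """Best-matching scenario id for one simulation (smallest trend index).

    Candidates are the hint-compatible trajectories at the grid cell nearest
    to the simulation's location; ties break to the lexicographically
    smallest scenario id.
    """
    cands = candidate_scenarios(meta, catalogue)
    cell = catalogue.nearest_cell(meta.latitude, meta.longitude)
    sim_slopes = trend_slopes(meta.annual_temperature, meta.annual_precipitation)
    best_id, best_d = None, math.inf
    for sid in cands:  # sorted: first minimum wins ties lexicographically
        traj = catalogue.trajectories[(sid, cell.cell_id)]
        idx = _overlap_index(meta.annual_temperature.index, traj)
        years = traj.years[idx]
        cand_slopes = trend_slopes(
            pd.Series(traj.annual_mat[idx], index=years),
            pd.Series(traj.annual_anp[idx], index=years),
        )
        d = trajectory_distance(sim_slopes, cand_slopes, weight)
        if d < best_d:
            best_id, best_d = sid, d
    return best_id


def adjust_trajectory(traj, sim_mat: float, sim_anp: float, sim_years=None):
    """Shift a trajectory to the simulation's temperature/precipitation level.

    Returns ``(adjusted, delta, factor)`` where ``delta`` (°C) is added to all
    daily temperatures and ``factor`` multiplies all daily precipitation, so
    that over the comparison period the adjusted trajectory's mean MAT equals
    ``sim_mat`` and its mean ANP equals ``sim_anp``.
    """
    idx = _overlap_index(sim_years, traj) if sim_years is not None else np.arange(len(traj.years))
    if len(idx) == 0:
        raise ValueError("no overlap between simulation and trajectory periods")
    traj_mat = float(traj.annual_mat[idx].mean())
    traj_anp = float(traj.annual_anp[idx].mean())
    if traj_anp <= 0:
        raise ValueError("trajectory precipitation is zero over the comparison period")
    delta = sim_mat - traj_mat
    factor = sim_anp / traj_anp
    if factor <= 0:
        raise ValueError(f"non-positive precipitation factor {factor}")
    adjusted = traj.replace(tas=traj.tas + delta, prec=traj.prec * factor)
    return adjusted, delta, factor


def year_distance(sim_year: tuple[float, float], scen_year: tuple[float, float],
                  weight: float = MATCH_WEIGHT) -> float:
    """Year-level matching index |ΔT| + 0.1·|100·(P_sim/P_scen − 1)|."""
    t_sim, p_sim = sim_year
    t_scen, p_scen = scen_year
    if p_sim <= 0 or p_scen <= 0:
        raise ValueError("annual precipitation must be > 0 for year matching")
    return abs(t_sim - t_scen) + weight * abs(100.0 * (p_sim / p_scen - 1.0))


def match_years(sim_annual: pd.DataFrame, adjusted_traj, rng: np.random.Generator,
                n_best: int = 3, weight: float = MATCH_WEIGHT) -> dict[int, int]:
    """Map each simulation year to one of its three best-matching scenario years.

    ``sim_annual`` has columns ``temperature`` and ``precipitation`` indexed
    by simulation year. For every simulation year the year-level index is
    computed against each scenario year; one of the ``n_best`` smallest
    (ties resolved toward earlier years) is sampled uniformly with
    replacement using ``rng``.
    """
    if len(adjusted_traj.years) < n_best:
        raise ValueError(f"trajectory must contain >= {n_best} years")
    scen_t = adjusted_traj.annual_mat
    scen_p = adjusted_traj.annual_anp
    mapping: dict[int, int] = {}
    for year, row in sim_annual.iterrows():
        d = np.array(
            [
                year_distance((row["temperature"], row["precipitation"]), (t, p), weight)
                for t, p in zip(scen_t, scen_p)
            ]
        )
        best = np.argsort(d, kind="stable")[:n_best]  # stable: ties -> earlier year
        pick = best[rng.integers(0, len(best))]
        mapping[int(year)] = int(adjusted_traj.years[pick])
    return mapping


def assemble_daily(adjusted_traj, mapping: dict[int, int], sim_year: int) -> dict[str, np.ndarray]:
    """Daily tas/prec/rad/vpd arrays (length 365) for one simulation year."""
    if sim_year not in mapping:
        raise KeyError(f"simulation year {sim_year} has no mapped scenario year")
    i = adjusted_traj.year_index(mapping[sim_year])
    return {
        "tas": adjusted_traj.tas[i].copy(),
        "prec": adjusted_traj.prec[i].copy(),
        "rad": adjusted_traj.rad[i].copy(),
        "vpd": adjusted_traj.vpd[i].copy(),
    }
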