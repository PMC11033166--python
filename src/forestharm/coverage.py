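"""Environmental-space stratification and coverage.

Climate space is stratified into mean-annual-temperature (MAT, 10 bins),
annual-precipitation (ANP, 7 bins) and temperature-seasonality (7 bins)
strata; soil space into texture class (coarse=1 .. very fine=5), water
holding capacity (5 bins) and plant-available nitrogen (5 bins). The
coverage of a reference area is the area-weighted fraction of reference
cells whose stratum is occupied by at least one simulation.

All printed interval lists share their endpoints, so every bin is treated
as half-open ``[low, high)``: a value on a boundary falls into the upper bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MAT_EDGES",
    "ANP_EDGES",
    "SEASONALITY_EDGES",
    "WHC_EDGES",
    "NITROGEN_EDGES",
    "ClimateStratum",
    "SoilStratum",
    "CoverageReport",
    "TextureThresholds",
    "seasonality",
    "climate_stratum",
    "texture_class",
    "soil_stratum",
    "coverage_fraction",
    "reference_from_grids",
]

# Stratification edges (units: °C, mm/yr, seasonality index, mm, kg/ha/yr).
MAT_EDGES = (-2.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 18.0)
ANP_EDGES = (400.0, 550.0, 750.0, 1000.0, 1400.0, 2000.0)
SEASONALITY_EDGES = (200.0, 400.0, 500.0, 600.0, 700.0, 900.0)
WHC_EDGES = (50.0, 100.0, 150.0, 180.0)
NITROGEN_EDGES = (20.0, 40.0, 65.0, 100.0)


@dataclass(frozen=True)
class ClimateStratum:
    mat_bin: int
    anp_bin: int
    seas_bin: int

    def __post_init__(self) -> None:
        if not (1 <= self.mat_bin <= len(MAT_EDGES) + 1):
            raise ValueError(f"mat_bin {self.mat_bin} out of range")
        if not (1 <= self.anp_bin <= len(ANP_EDGES) + 1):
            raise ValueError(f"anp_bin {self.anp_bin} out of range")
        if not (1 <= self.seas_bin <= len(SEASONALITY_EDGES) + 1):
            raise ValueError(f"seas_bin {self.seas_bin} out of range")


@dataclass(frozen=True)
class SoilStratum:
    texture_class: int
    whc_bin: int
    n_bin: int

    def __post_init__(self) -> None:
        if not (1 <= self.texture_class <= 5):
            raise ValueError(f"texture_class {self.texture_class} out of range")
        if not (1 <= self.whc_bin <= len(WHC_EDGES) + 1):
            raise ValueError(f"whc_bin {self.whc_bin} out of range")
        if not (1 <= self.n_bin <= len(NITROGEN_EDGES) + 1):
            raise ValueError(f"n_bin {self.n_bin} out of range")


@dataclass(frozen=True)
class TextureThresholds:
    """Clay/sand percentage thresholds of the 5-class texture scheme.

    Orientation follows the European Soil Database convention used here:
    1 = coarse, 5 = very fine. Applied in order: very fine, fine,
    medium fine, coarse, else medium.
    """

    very_fine_clay: float = 60.0
    fine_clay: float = 35.0
    medium_fine_sand: float = 15.0
    coarse_clay: float = 18.0
    coarse_sand: float = 65.0


@dataclass
class CoverageReport:
    occupied: set
    fraction: float  # percent of reference area
    per_stratum_weight: pd.Series  # total weight per reference stratum


def _bin_index(value: float, edges: Sequence[float]) -> int:
    """1-based half-open bin index; ``value == edge`` goes to the upper bin."""
    return int(np.searchsorted(edges, value, side="right")) + 1


def seasonality(monthly_means: Sequence[float]) -> float:
    """Temperature seasonality: population sd of 12 monthly means × 100."""
    arr = np.asarray(monthly_means, dtype=float)
    if arr.shape != (12,):
        raise ValueError(f"expected 12 monthly means, got shape {arr.shape}")
    return float(np.std(arr) * 100.0)


def climate_stratum(mat: float, anp: float, seas: float) -> ClimateStratum:
    """Assign MAT (°C), ANP (mm/yr) and seasonality to their climate stratum."""
    for name, v in (("mat", mat), ("anp", anp), ("seas", seas)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    return ClimateStratum(
        mat_bin=_bin_index(mat, MAT_EDGES),
        anp_bin=_bin_index(anp, ANP_EDGES),
        seas_bin=_bin_index(seas, SEASONALITY_EDGES),
    )


def texture_class(
    sand: float, silt: float, clay: float, thresholds: TextureThresholds | None = None
) -> int:
    """Five-class soil texture from sand/silt/clay percentages (1 coarse .. 5 very fine)."""
    if abs(sand + silt + clay - 100.0) > 1.0:
        raise ValueError(f"texture fractions must sum to 100 ± 1, got {sand + silt + clay}")
    t = thresholds or TextureThresholds()
    if clay >= t.very_fine_clay:
        return 5
    if clay >= t.fine_clay:
        return 4
    if sand <= t.medium_fine_sand:
        return 3
    if clay < t.coarse_clay and sand > t.coarse_sand:
        return 1
    return 2


def soil_stratum(texture: int, whc: float, available_n: float) -> SoilStratum:
    """Assign texture class, WHC (mm) and available N (kg/ha/yr) to their soil stratum."""
    for name, v in (("whc", whc), ("available_n", available_n)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    return SoilStratum(
        texture_class=int(texture),
        whc_bin=_bin_index(whc, WHC_EDGES),
        n_bin=_bin_index(available_n, NITROGEN_EDGES),
    )


def coverage_fraction(occupied: Iterable, reference: pd.DataFrame) -> float:
    """Percent of reference area whose stratum is in the occupied set.

    ``reference`` needs a ``stratum`` column (hashable stratum objects) and a
    positive ``weight`` column; area weights (e.g. cos of latitude) are the
    caller's responsibility.
    """
    if len(reference) == 0:
        raise ValueError("reference grid is empty")
    weights = reference["weight"].to_numpy(dtype=float)
    if np.any(weights <= 0):
        raise ValueError("reference weights must be > 0")
    occupied = set(occupied)
    covered = reference["stratum"].map(lambda s: s in occupied).to_numpy()
    return float(100.0 * weights[covered].sum() / weights.sum())


def reference_from_grids(grids) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build climate and soil reference tables from a soil/climate grid stack.

    Returns ``(climate_ref, soil_ref)`` data frames with ``stratum`` and
    cos(latitude) ``weight`` columns, one row per grid cell.
    """
    from . import soil as _soil  # local import to avoid a cycle

    lats = grids["lat"].values
    lons = grids["lon"].values
    clim_rows = []
    soil_rows = []
    for i, lat in enumerate(lats):
        w = math.cos(math.radians(float(lat)))
        for j, lon in enumerate(lons):
            cell = grids.isel(lat=i, lon=j)
            cs = climate_stratum(
                float(cell["mat"]), float(cell["anp"]), float(cell["seasonality"])
            )
            if "available_n_true" in grids:
                avail = float(cell["available_n_true"])
            else:
                avail = _soil.reclassify_fertility(int(cell["sq1"]))
            tex = texture_class(float(cell["sand"]), float(cell["silt"]), float(cell["clay"]))
            ss = soil_stratum(tex, float(cell["whc"]), avail)
            clim_rows.append({"lat": float(lat), "lon": float(lon), "stratum": cs, "weight": w})
            soil_rows.append({"lat": float(lat), "lon": float(lon), "stratum": ss, "weight": w})
    return pd.DataFrame(clim_rows), pd.DataFrame(soil_rows)
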