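"""Quantitative soil vectors and the pseudo-mineralization GLM.

Plant-available nitrogen — the annual flux of mineralized nitrogen — is not
mapped at continental scale, so it is approximated in three steps:

1. an ordinal soil-fertility class (SQ1-style, 1 = highest availability) is
   reclassified to a nominal availability of 100 / 65 / 40 / 20 kg/ha/yr;
2. dividing by the topsoil (0–30 cm) nitrogen pool gives a coarse
   pseudo-mineralization rate (1/yr), which is regressed on mean annual
   temperature, annual precipitation, temperature seasonality and soil pH
   with a Gamma GLM (log link);
3. multiplying the modelled rate back with the pool yields a smooth,
   climate-consistent estimate of plant-available nitrogen.

The module also completes per-simulation soil vectors (WHC, texture, depth,
available N) from metadata, descriptive ratings, and gridded layers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DEFAULT_FERTILITY_RECLASS",
    "DEFAULT_WATER_RATING",
    "DEFAULT_FERTILITY_RATING",
    "SoilVector",
    "RateGLM",
    "reclassify_fertility",
    "nitrogen_pool",
    "pseudo_rate",
    "fit_rate_glm",
    "predict_rate",
    "predict_available_n",
    "complete_soil_vector",
    "rates_from_grids",
]

#: Fertility class (1 = highest availability) → plant-available N (kg/ha/yr).
DEFAULT_FERTILITY_RECLASS = {1: 100.0, 2: 65.0, 3: 40.0, 4: 20.0}

#: Five-level descriptive water rating → water holding capacity (mm).
DEFAULT_WATER_RATING = {
    "very dry": 40.0,
    "dry": 80.0,
    "mesic": 120.0,
    "moist": 160.0,
    "wet": 200.0,
}

#: Five-level descriptive fertility rating → plant-available N (kg/ha/yr).
DEFAULT_FERTILITY_RATING = {
    "very poor": 20.0,
    "poor": 40.0,
    "medium": 65.0,
    "rich": 100.0,
    "very rich": 120.0,
}

POOL_DEPTH_M = 0.30  # topsoil depth over which the nitrogen pool is integrated

GLM_COVARIATES = ("mat", "anp", "seasonality", "ph")


@dataclass(frozen=True)
class SoilVector:
    """Complete quantitative soil description of one location."""

    whc: float  # mm
    sand: float  # %
    silt: float  # %
    clay: float  # %
    depth: float  # mm
    available_n: float  # kg/ha/yr

    def __post_init__(self) -> None:
        tex = self.sand + self.silt + self.clay
        if abs(tex - 100.0) > 1.0:
            raise ValueError(f"texture fractions sum to {tex}, expected 100 ± 1")
        for name in ("whc", "sand", "silt", "clay", "depth", "available_n"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class RateGLM:
    """Fitted pseudo-mineralization rate model (Gamma family, log link)."""

    coefficients: pd.Series  # index: const + GLM_COVARIATES
    deviance_explained: float  # D² = 1 − residual deviance / null deviance
    family: str = "gamma"
    link: str = "log"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coefficients.to_numpy(dtype=float))):
            raise ValueError("GLM coefficients must be finite")


def reclassify_fertility(sq1_class: int, table: dict[int, float] | None = None) -> float:
    """Map an ordinal fertility class (1 highest .. 4 lowest) to kg/ha/yr."""
    table = table or DEFAULT_FERTILITY_RECLASS
    if sq1_class not in table:
        raise ValueError(f"fertility class {sq1_class} outside {sorted(table)}")
    return float(table[sq1_class])


def nitrogen_pool(layers) -> float:
    """Topsoil nitrogen pool (kg/ha) from per-layer content and bulk density.

    ``layers`` is an iterable of ``(n_content g/kg, bulk_density kg/m³,
    top m, bottom m)``; layers crossing 0.30 m are truncated there and layers
    entirely below are ignored. 1 kg/m² = 10,000 kg/ha.
    """
    pool_kg_m2 = 0.0
    for n_content, bulk_density, top, bottom in layers:
        if n_content < 0 or bulk_density < 0:
            raise ValueError("nitrogen content and bulk density must be >= 0")
        if bottom < top:
            raise ValueError(f"layer bottom {bottom} above top {top}")
        top_t = min(top, POOL_DEPTH_M)
        bottom_t = min(bottom, POOL_DEPTH_M)
        thickness = bottom_t - top_t
        # g/kg × kg/m³ × m = g/m² → /1000 = kg/m²
        pool_kg_m2 += n_content * bulk_density * thickness / 1000.0
    return pool_kg_m2 * 10_000.0


def pseudo_rate(fertility: float, pool: float) -> float:
    """Pseudo-mineralization rate (1/yr): availability flux over pool."""
    if pool <= 0:
        raise ValueError(f"nitrogen pool must be > 0, got {pool}")
    return fertility / pool


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GLM_COVARIATES if c not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    return sm.add_constant(covariates[list(GLM_COVARIATES)], has_constant="add")


def fit_rate_glm(rates, covariates: pd.DataFrame) -> RateGLM:
    """Calibrate the Gamma/log GLM of pseudo-mineralization rate on climate and pH.

    ``rates`` is a positive series (1/yr) aligned with ``covariates`` rows
    (columns ``mat`` °C, ``anp`` mm, ``seasonality``, ``ph``). Requires at
    least 50 observations. Reports the deviance explained D².
    """
    y = np.asarray(rates, dtype=float)
    if len(y) < 50:
        raise ValueError(f"need >= 50 cells to calibrate the rate GLM, got {len(y)}")
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("rates must be positive and finite")
    X = _design_matrix(covariates.reset_index(drop=True))
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    try:
        with warnings.catch_warnings():
            # Gamma/log IRLS flags near-exact fits as "perfect separation"
            warnings.simplefilter("ignore")
            result = model.fit()
    except Exception as exc:  # statsmodels raises several convergence errors
        raise RuntimeError(f"rate GLM failed to converge: {exc}") from exc
    if not np.all(np.isfinite(result.params)):
        raise RuntimeError("rate GLM produced non-finite coefficients")
    d2 = 1.0 - result.deviance / result.null_deviance if result.null_deviance > 0 else 1.0
    return RateGLM(coefficients=pd.Series(result.params, index=X.columns), deviance_explained=d2)


def predict_rate(covariates: pd.DataFrame, model: RateGLM):
    """Predicted pseudo-mineralization rate (1/yr) under the log link."""
    X = _design_matrix(pd.DataFrame(covariates))
    eta = X.to_numpy(dtype=float) @ model.coefficients.reindex(X.columns).to_numpy(dtype=float)
    return np.exp(eta)


def predict_available_n(pool: float, covariates, model: RateGLM) -> float:
    """Plant-available nitrogen (kg/ha/yr): pool × modelled rate."""
    if pool < 0:
        raise ValueError(f"pool must be >= 0, got {pool}")
    cov = pd.DataFrame([covariates]) if isinstance(covariates, dict) else pd.DataFrame(covariates)
    rate = float(predict_rate(cov, model)[0])
    return pool * rate


def rates_from_grids(grids, reclass_table: dict[int, float] | None = None) -> pd.DataFrame:
    """Per-cell calibration table (rate + covariates) from a soil grid stack.

    The observed rate at each cell is the reclassified fertility class divided
    by the topsoil nitrogen pool computed from the grid's layers.
    """
    n_layers = grids.sizes["layer"]
    tops = grids["layer_top"].values
    bottoms = grids["layer_bottom"].values
    rows = []
    for i in range(grids.sizes["lat"]):
        for j in range(grids.sizes["lon"]):
            cell = grids.isel(lat=i, lon=j)
            pool = nitrogen_pool(
                [
                    (
                        float(cell["n_content"].isel(layer=k)),
                        float(cell["bulk_density"].isel(layer=k)),
                        float(tops[k]),
                        float(bottoms[k]),
                    )
                    for k in range(n_layers)
                ]
            )
            fert = reclassify_fertility(int(cell["sq1"]), reclass_table)
            rows.append(
                {
                    "lat": float(grids["lat"].values[i]),
                    "lon": float(grids["lon"].values[j]),
                    "pool": pool,
                    "rate": pseudo_rate(fert, pool),
                    "mat": float(cell["mat"]),
                    "anp": float(cell["anp"]),
                    "seasonality": float(cell["seasonality"]),
                    "ph": float(cell["ph"]),
                }
            )
    return pd.DataFrame(rows)


def _nearest_cell(grids, latitude: float, longitude: float):
    lat_min, lat_max = float(grids["lat"].min()), float(grids["lat"].max())
    lon_min, lon_max = float(grids["lon"].min()), float(grids["lon"].max())
    res = float(grids.attrs.get("resolution", 0.11))
    inside = (
        lat_min - res <= latitude <= lat_max + res
        and lon_min - res <= longitude <= lon_max + res
    )
    cell = grids.sel(lat=latitude, lon=longitude, method="nearest") if inside else None
    return cell, inside


def complete_soil_vector(
    meta,
    grids,
    model: RateGLM,
    water_rating: dict[str, float] | None = None,
    fertility_rating: dict[str, float] | None = None,
) -> SoilVector:
    """Complete one simulation's soil vector from metadata, ratings and grids.

    Numeric metadata fields are used verbatim; descriptive ratings are
    converted through the ordinal lookups; anything still missing is filled
    from the nearest grid cell, with available N modelled by the rate GLM when
    no measurement or rating exists. Raises when a field is missing and the
    location lies outside the grids.
    """
    water_rating = water_rating or DEFAULT_WATER_RATING
    fertility_rating = fertility_rating or DEFAULT_FERTILITY_RATING

    cell, inside = _nearest_cell(grids, meta.latitude, meta.longitude)

    def grid_value(field: str) -> float:
        if not inside:
            raise ValueError(
                f"simulation {meta.simulation_id}: field {field!r} missing and location "
                f"({meta.latitude}, {meta.longitude}) outside the soil grids"
            )
        return float(cell[field])

    def present(value) -> bool:
        return value is not None and not (isinstance(value, float) and math.isnan(value))

    whc = meta.whc
    if not present(whc):
        rating = getattr(meta, "water_rating", None)
        if present(rating) and str(rating) in water_rating:
            whc = water_rating[str(rating)]
        else:
            whc = grid_value("whc")

    if present(meta.sand) and present(meta.silt) and present(meta.clay):
        sand, silt, clay = float(meta.sand), float(meta.silt), float(meta.clay)
    else:
        sand, silt, clay = grid_value("sand"), grid_value("silt"), grid_value("clay")

    depth = meta.depth if present(meta.depth) else grid_value("depth")

    available_n = meta.available_n
    if not present(available_n):
        rating = getattr(meta, "fertility_rating", None)
        if present(rating) and str(rating) in fertility_rating:
            available_n = fertility_rating[str(rating)]
        else:
            if not inside:
                raise ValueError(
                    f"simulation {meta.simulation_id}: field 'available_n' missing and "
                    f"location outside the soil grids"
                )
            pool = nitrogen_pool(
                [
                    (
                        float(cell["n_content"].isel(layer=k)),
                        float(cell["bulk_density"].isel(layer=k)),
                        float(grids["layer_top"].isel(layer=k)),
                        float(grids["layer_bottom"].isel(layer=k)),
                    )
                    for k in range(grids.sizes["layer"])
                ]
            )
            covs = {
                "mat": float(cell["mat"]),
                "anp": float(cell["anp"]),
                "seasonality": float(cell["seasonality"]),
                "ph": float(cell["ph"]),
            }
            available_n = predict_available_n(pool, covs, model)

    return SoilVector(
        whc=float(whc),
        sand=float(sand),
        silt=float(silt),
        clay=float(clay),
        depth=float(depth),
        available_n=float(available_n),
    )
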