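"""Dominant stand height from heterogeneous height statistics.

Forest simulators report different canopy height statistics (any subset of
minimum, mean and maximum height). Harmonization to dominant stand height —
the height of the tallest stratum — proceeds by:

* filling a missing mean as the arithmetic mean of minimum and maximum;
* filling a missing maximum from the mean with a linear mixed model
  (max ~ mean, per-species random intercept and slope);
* predicting dominant height from mean and maximum, either through a
  per-species allometric factor on maximum height (for the six species with
  published yield-table factors) or through a linear mixed model
  (dominant ~ mean + max with per-species random slopes);
* clamping the result to [0.8 · max, max] to be robust to outliers.

Mixed models are fitted by REML via statsmodels; exactly collinear
(noise-free) calibration data degenerates the REML profile, in which case
the per-species least-squares solution is returned directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "KAHN_SPECIES",
    "DEFAULT_ALLOMETRIC_FACTORS",
    "HeightStatistics",
    "MaxHeightModel",
    "DominantHeightModel",
    "SingularFitError",
    "mean_from_min_max",
    "fit_max_from_mean",
    "predict_max_from_mean",
    "fit_dominant_model",
    "dominant_height",
]

#: Species with published allometric dominant-height factors.
KAHN_SPECIES = (
    "Pinus sylvestris",
    "Abies alba",
    "Larix decidua",
    "Picea abies",
    "Fagus sylvatica",
    "Quercus robur",
)

#: Placeholder dominant = factor × max factors; replace from config with the
#: published per-species values when available.
DEFAULT_ALLOMETRIC_FACTORS = {s: 0.95 for s in KAHN_SPECIES}

CLAMP_LOWER = 0.8  # dominant height >= 0.8 × maximum height

_EXACT_TOL = 1e-9


class SingularFitError(RuntimeError):
    """Mixed-model fit failed; carries the underlying diagnostics message."""


@dataclass(frozen=True)
class HeightStatistics:
    """Per-stand-year height statistics (m); any subset may be present."""

    min: float | None = None
    mean: float | None = None
    max: float | None = None

    def __post_init__(self) -> None:
        present = [(k, v) for k, v in (("min", self.min), ("mean", self.mean), ("max", self.max)) if v is not None]
        for k, v in present:
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"height {k} must be finite and >= 0, got {v}")
        vals = dict(present)
        if "min" in vals and "mean" in vals and vals["min"] > vals["mean"] + 1e-9:
            raise ValueError(f"min {vals['min']} > mean {vals['mean']}")
        if "mean" in vals and "max" in vals and vals["mean"] > vals["max"] + 1e-9:
            raise ValueError(f"mean {vals['mean']} > max {vals['max']}")
        if "min" in vals and "max" in vals and vals["min"] > vals["max"] + 1e-9:
            raise ValueError(f"min {vals['min']} > max {vals['max']}")


def mean_from_min_max(height_min: float, height_max: float) -> float:
    """Arithmetic mean of minimum and maximum height."""
    if height_min < 0 or height_min > height_max:
        raise ValueError(f"need 0 <= min <= max, got min={height_min}, max={height_max}")
    return (height_min + height_max) / 2.0


@dataclass
class MaxHeightModel:
    """max ~ mean with per-species random intercept and slope."""

    intercept: float
    slope: float
    species_effects: dict[str, tuple[float, float]]  # species -> (Δintercept, Δslope)
    resid_sd: float
    r2_marginal: float
    r2_conditional: float

    def linear_predictor(self, mean: float, species: str | None) -> float:
        di, ds = self.species_effects.get(species, (0.0, 0.0))
        return (self.intercept + di) + (self.slope + ds) * mean


@dataclass
class DominantHeightModel:
    """dominant ~ mean + max with per-species random slopes on both predictors."""

    intercept: float
    coef_mean: float
    coef_max: float
    species_effects: dict[str, tuple[float, float]]  # species -> (Δcoef_mean, Δcoef_max)
    resid_sd: float
    r2_marginal: float
    r2_conditional: float
    allometric_factors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALLOMETRIC_FACTORS))

    def linear_predictor(self, mean: float, max_: float, species: str | None) -> float:
        dm, dx = self.species_effects.get(species, (0.0, 0.0))
        return self.intercept + (self.coef_mean + dm) * mean + (self.coef_max + dx) * max_


def _check_calibration(table: pd.DataFrame, required: list[str]) -> pd.DataFrame:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"calibration table lacks columns {missing}")
    df = table[required].dropna().copy()
    counts = df.groupby("species").size()
    if len(counts) < 2:
        raise SingularFitError(
            f"need >= 2 species to identify random effects, got {len(counts)}"
        )
    if (counts < 3).any():
        raise ValueError(f"need >= 3 rows per species, offending: {list(counts[counts < 3].index)}")
    return df


def _per_species_ols(df: pd.DataFrame, y: str, xs: list[str]) -> tuple[dict, float]:
    """Per-species OLS (with intercept); returns coefficients and max residual."""
    out = {}
    worst = 0.0
    for sp, g in df.groupby("species"):
        X = np.column_stack([np.ones(len(g))] + [g[x].to_numpy(dtype=float) for x in xs])
        yv = g[y].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        worst = max(worst, float(np.max(np.abs(resid))) if len(resid) else 0.0)
        out[sp] = beta
    return out, worst


def _nakagawa_r2(df: pd.DataFrame, fixed_pred: np.ndarray, full_pred: np.ndarray, resid_var: float):
    var_f = float(np.var(fixed_pred))
    var_r = float(np.var(full_pred - fixed_pred))
    denom = var_f + var_r + resid_var
    if denom <= 0:
        return 1.0, 1.0
    return var_f / denom, (var_f + var_r) / denom


def fit_max_from_mean(calibration: pd.DataFrame) -> MaxHeightModel:
    """Calibrate max ~ mean with per-species random effects.

    The calibration table needs columns ``species``, ``height_mean`` and
    ``height_max`` with at least two species and three rows per species.
    """
    df = _check_calibration(calibration, ["species", "height_mean", "height_max"])
    ols, worst = _per_species_ols(df, "height_max", ["height_mean"])
    if worst < _EXACT_TOL * max(1.0, float(df["height_max"].abs().max())):
        # exact per-species linear data: REML is degenerate, return the LS solution
        betas = np.array(list(ols.values()))
        fixed = betas.mean(axis=0)
        effects = {sp: (b[0] - fixed[0], b[1] - fixed[1]) for sp, b in ols.items()}
        return MaxHeightModel(
            intercept=float(fixed[0]), slope=float(fixed[1]), species_effects=effects,
            resid_sd=0.0, r2_marginal=float("nan"), r2_conditional=1.0,
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "height_max ~ height_mean", df, groups=df["species"], re_formula="~height_mean"
            )
            result = model.fit(reml=True)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise SingularFitError(f"max-height mixed model failed: {exc}") from exc
    if not np.all(np.isfinite(result.fe_params)):
        raise SingularFitError("max-height mixed model produced non-finite fixed effects")
    effects = {
        sp: (float(re.get("Group", 0.0)), float(re.get("height_mean", 0.0)))
        for sp, re in result.random_effects.items()
    }
    intercept, slope = float(result.fe_params.iloc[0]), float(result.fe_params.iloc[1])
    mean_arr = df["height_mean"].to_numpy(dtype=float)
    fixed_pred = intercept + slope * mean_arr
    full_pred = np.array(
        [intercept + effects[sp][0] + (slope + effects[sp][1]) * m for sp, m in zip(df["species"], mean_arr)]
    )
    r2m, r2c = _nakagawa_r2(df, fixed_pred, full_pred, float(result.scale))
    return MaxHeightModel(
        intercept=intercept, slope=slope, species_effects=effects,
        resid_sd=float(np.sqrt(result.scale)), r2_marginal=r2m, r2_conditional=r2c,
    )


def predict_max_from_mean(mean: float, species: str | None, model: MaxHeightModel) -> float:
    """Predict maximum from mean height; unseen species get the fixed effects.

    The prediction is floored at the mean to preserve the physical ordering.
    """
    if mean < 0:
        raise ValueError(f"mean height must be >= 0, got {mean}")
    return max(model.linear_predictor(mean, species), mean)


def fit_dominant_model(calibration: pd.DataFrame) -> DominantHeightModel:
    """Calibrate dominant ~ mean + max with per-species random slopes.

    The calibration table needs columns ``species``, ``height_mean``,
    ``height_max`` and ``dominant_height``.
    """
    df = _check_calibration(
        calibration, ["species", "height_mean", "height_max", "dominant_height"]
    )
    ols, worst = _per_species_ols(df, "dominant_height", ["height_mean", "height_max"])
    if worst < _EXACT_TOL * max(1.0, float(df["dominant_height"].abs().max())):
        betas = np.array(list(ols.values()))
        fixed = betas.mean(axis=0)
        effects = {sp: (b[1] - fixed[1], b[2] - fixed[2]) for sp, b in ols.items()}
        return DominantHeightModel(
            intercept=float(fixed[0]), coef_mean=float(fixed[1]), coef_max=float(fixed[2]),
            species_effects=effects, resid_sd=0.0, r2_marginal=float("nan"), r2_conditional=1.0,
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "dominant_height ~ height_mean + height_max",
                df,
                groups=df["species"],
                re_formula="0 + height_mean + height_max",
            )
            result = model.fit(reml=True)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise SingularFitError(f"dominant-height mixed model failed: {exc}") from exc
    if not np.all(np.isfinite(result.fe_params)):
        raise SingularFitError("dominant-height mixed model produced non-finite fixed effects")
    effects = {
        sp: (float(re.get("height_mean", 0.0)), float(re.get("height_max", 0.0)))
        for sp, re in result.random_effects.items()
    }
    intercept = float(result.fe_params.iloc[0])
    coef_mean = float(result.fe_params["height_mean"])
    coef_max = float(result.fe_params["height_max"])
    mean_arr = df["height_mean"].to_numpy(dtype=float)
    max_arr = df["height_max"].to_numpy(dtype=float)
    fixed_pred = intercept + coef_mean * mean_arr + coef_max * max_arr
    full_pred = np.array(
        [
            intercept + (coef_mean + effects[sp][0]) * m + (coef_max + effects[sp][1]) * x
            for sp, m, x in zip(df["species"], mean_arr, max_arr)
        ]
    )
    r2m, r2c = _nakagawa_r2(df, fixed_pred, full_pred, float(result.scale))
    return DominantHeightModel(
        intercept=intercept, coef_mean=coef_mean, coef_max=coef_max,
        species_effects=effects, resid_sd=float(np.sqrt(result.scale)),
        r2_marginal=r2m, r2_conditional=r2c,
    )


def dominant_height(
    stats: HeightStatistics,
    species: str | None,
    dominant_model: DominantHeightModel,
    max_model: MaxHeightModel,
    allometric_factors: dict[str, float] | None = None,
) -> float:
    """Harmonize height statistics to dominant stand height (m).

    Dispatch: with mean and max available, stands of one of the six
    allometric-factor species use dominant = factor × max, every other
    species the mixed model; min+max fills the mean arithmetically and
    mean-only fills the max via the max-height model. The result is clamped
    to [0.8 × max, max].
    """
    factors = allometric_factors if allometric_factors is not None else dominant_model.allometric_factors
    mean, mx = stats.mean, stats.max
    if mean is None and stats.min is not None and mx is not None:
        mean = mean_from_min_max(stats.min, mx)
    if mean is None:
        raise ValueError("no usable height statistic: need mean, or min and max")
    if mx is None:
        mx = predict_max_from_mean(mean, species, max_model)
    if species is not None and species in factors:
        raw = factors[species] * mx
    else:
        raw = dominant_model.linear_predictor(mean, mx, species)
    return float(min(max(raw, CLAMP_LOWER * mx), mx))
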