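"""Pipeline configuration: every tunable constant of the harmonization.

The configuration is one human-readable YAML file; command-line flags
override individual fields, and each run writes the resolved configuration
next to its outputs for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .heights import DEFAULT_ALLOMETRIC_FACTORS
from .soil import DEFAULT_FERTILITY_RECLASS, DEFAULT_WATER_RATING, DEFAULT_FERTILITY_RATING

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All paths, seeds and constants of one harmonization run."""

    contributions: list[dict] = field(default_factory=list)  # [{"sim": path, "meta": path}]
    catalogue: str = ""
    soil_grids: str = ""
    height_calibration: str = ""
    out_dir: str = "harmonized"
    seed: int = 0
    matching_weight: float = 0.1
    dominance_threshold: float = 0.66
    admixture_threshold: float = 0.20
    lai_edges: tuple[float, float] = (2.0, 4.0)
    height_bin_width: int = 2
    fertility_reclass: dict = field(default_factory=lambda: dict(DEFAULT_FERTILITY_RECLASS))
    water_rating_lookup: dict = field(default_factory=lambda: dict(DEFAULT_WATER_RATING))
    fertility_rating_lookup: dict = field(default_factory=lambda: dict(DEFAULT_FERTILITY_RATING))
    allometric_factors: dict = field(default_factory=lambda: dict(DEFAULT_ALLOMETRIC_FACTORS))

    def validate(self) -> None:
        if not (0 < self.dominance_threshold < 1):
            raise ValueError(f"dominance threshold must be in (0,1), got {self.dominance_threshold}")
        if not (0 < self.admixture_threshold < 1):
            raise ValueError(f"admixture threshold must be in (0,1), got {self.admixture_threshold}")
        if self.height_bin_width <= 0:
            raise ValueError("height bin width must be > 0")
        if self.matching_weight < 0:
            raise ValueError("matching weight must be >= 0")
        lo, hi = self.lai_edges
        if not lo < hi:
            raise ValueError(f"LAI class edges must increase, got {self.lai_edges}")
        for name in ("catalogue", "soil_grids", "height_calibration"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        for c in self.contributions:
            for k in ("sim", "meta"):
                if not Path(c[k]).exists():
                    raise FileNotFoundError(f"contribution file does not exist: {c[k]}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "lai_edges" in raw:
            raw["lai_edges"] = tuple(raw["lai_edges"])
        if "fertility_reclass" in raw:
            raw["fertility_reclass"] = {int(k): float(v) for k, v in raw["fertility_reclass"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["lai_edges"] = list(self.lai_edges)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
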