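"""Pipeline configuration: every tunable parameter in one serializable place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .structure import StructureParams
from .tracking import TrackingParams


@dataclass
class PipelineConfig:
    """All pipeline parameters with their defaults.

    Round-trips through YAML/JSON (``save``/``load``); construction
    validates ranges so a config file with an out-of-range value fails
    loudly rather than producing nonsense traits.
    """

    # cloud preparation
    scale_mm: float = 1.0            # mm per input unit
    align: bool = True
    # level-set scan
    thickness: float = 1.0           # mm
    pixel_mm: float = 0.5            # mm per pixel
    interp_frames: int = 2           # k intermediate frames per slice gap
    # per-slice detection
    min_component_area: int = 2      # px^2
    watershed_min_distance: int = 5  # px
    merge_ridge_ratio: float = 0.9
    snake_refine: bool = False
    snake_alpha: float = 0.015
    snake_beta: float = 0.1
    snake_max_iter: int = 500
    # tracking / structure
    tracking: TrackingParams = field(default_factory=TrackingParams)
    structure: StructureParams = field(default_factory=StructureParams)
    # descriptor
    descriptor_grid: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.scale_mm <= 0 or self.thickness <= 0 or self.pixel_mm <= 0:
            raise ValueError("scale_mm, thickness and pixel_mm must be positive")
        if self.interp_frames < 0:
            raise ValueError("interp_frames must be >= 0")
        if self.descriptor_grid < 2:
            raise ValueError("descriptor_grid must be >= 2")
        if self.tracking.gate <= 0 or self.tracking.max_skip < 0:
            raise ValueError("invalid tracking parameters")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "tracking" in d and isinstance(d["tracking"], dict):
            d["tracking"] = TrackingParams(**d["tracking"])
        if "structure" in d and isinstance(d["structure"], dict):
            d["structure"] = StructureParams(**d["structure"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=1) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=True))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        d = (json.loads(path.read_text()) if path.suffix == ".json"
             else yaml.safe_load(path.read_text()))
        return cls.from_dict(d)
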