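"""Run configuration: YAML round-trippable description of a full pipeline run."""
from __future__ import annotations

import dataclasses
import os

import yaml

from .errors import InvalidParameterError
from .movement import IBMMConfig
from .terrain import SxConfig
from .updraft import WindScenario

__all__ = ["SyntheticTerrainSpec", "RunConfig"]


@dataclasses.dataclass(frozen=True)
class SyntheticTerrainSpec:
    """Parameters for generating terrain instead of loading a DEM file.

    ``kind`` is one of ``ridge``, ``plane``, ``flat``; the remaining fields
    mirror the generator arguments.
    """

    kind: str = "ridge"
    nrows: int = 128
    ncols: int = 128
    dx: float = 30.0
    peak_height: float = 100.0
    width_sigma: float = 200.0
    azimuth: float = 0.0
    gradient: float = 0.1
    base_elevation: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ridge", "plane", "flat"):
            raise InvalidParameterError(f"unknown synthetic terrain kind {self.kind!r}")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one terrain -> updraft -> movement run."""

    scenarios: tuple[WindScenario, ...]
    heights: tuple[float, ...]
    out_dir: str
    dem_path: str | None = None
    synthetic: SyntheticTerrainSpec | None = None
    model: str = "evve"
    clip_negative: bool = False
    fill_nodata: bool = False
    sx: SxConfig = dataclasses.field(default_factory=SxConfig)
    ibmm: IBMMConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.dem_path is None) == (self.synthetic is None):
            raise InvalidParameterError("exactly one of dem_path / synthetic must be given")
        if self.dem_path is not None and not os.path.exists(self.dem_path):
            raise InvalidParameterError(f"DEM path does not exist: {self.dem_path}")
        if not self.heights or any(h <= 0 for h in self.heights):
            raise InvalidParameterError("heights must be a non-empty list of positive values")
        if self.model not in ("evve", "bo04"):
            raise InvalidParameterError(f"unknown model {self.model!r}")
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        object.__setattr__(self, "heights", tuple(float(h) for h in self.heights))

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "scenarios": [{"wdir": s.wdir, "v_ref": s.v_ref} for s in self.scenarios],
            "heights": list(self.heights),
            "out_dir": self.out_dir,
            "model": self.model,
            "clip_negative": self.clip_negative,
            "fill_nodata": self.fill_nodata,
            "sx": dataclasses.asdict(self.sx),
            "seed": self.seed,
        }
        if self.dem_path is not None:
            d["dem_path"] = self.dem_path
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        if self.ibmm is not None:
            d["ibmm"] = dataclasses.asdict(self.ibmm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            scenarios=tuple(WindScenario(**s) for s in d["scenarios"]),
            heights=tuple(d["heights"]),
            out_dir=d["out_dir"],
            dem_path=d.get("dem_path"),
            synthetic=SyntheticTerrainSpec(**d["synthetic"]) if "synthetic" in d else None,
            model=d.get("model", "evve"),
            clip_negative=d.get("clip_negative", False),
            fill_nodata=d.get("fill_nodata", False),
            sx=SxConfig(**d.get("sx", {})),
            ibmm=IBMMConfig(**d["ibmm"]) if "ibmm" in d else None,
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
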