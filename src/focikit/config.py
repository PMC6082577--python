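"""Pipeline configuration with a strict schema.

Every tunable of the pipeline lives in one config object so runs are
reproducible from a single file; unknown keys are rejected rather than
silently ignored, which guards against parameter drift through typos.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .dynamics import RenderWindow
from .segmentation import SegmentationParams
from .synthetic import SceneSpec

__all__ = ["PipelineConfig", "TrackingParams", "StatisticsParams", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class QuantificationParams:
    annulus_width_px: int = 1
    exclude_other_foci: bool = True


@dataclass(frozen=True)
class TrackingParams:
    link_radius_px: float = 15.0
    max_gap: int = 1
    site_radius_px: float = 3.0
    static_threshold: float = 0.7


@dataclass(frozen=True)
class StatisticsParams:
    alpha: float = 0.05
    percentile_method: str = "linear"
    posthoc: str = "holm"


@dataclass(frozen=True)
class SegmentationConfig:
    k_sd: float = 2.2
    min_size_px: int = 6
    connectivity: int = 8
    mode: str = "2d"
    exclude_boundary_foci: bool = False

    def params(self) -> SegmentationParams:
        return SegmentationParams(
            k_sd=self.k_sd,
            min_size_px=self.min_size_px,
            connectivity=self.connectivity,
            exclude_boundary_foci=self.exclude_boundary_foci,
        )


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    coerced = dict(data)
    for f in fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


@dataclass(frozen=True)
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    quantification: QuantificationParams = field(default_factory=QuantificationParams)
    render: RenderWindow = field(default_factory=RenderWindow)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    statistics: StatisticsParams = field(default_factory=StatisticsParams)
    scenes: dict = field(default_factory=dict)  # name -> SceneSpec
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
        kwargs = {}
        sections = {
            "segmentation": SegmentationConfig,
            "quantification": QuantificationParams,
            "render": RenderWindow,
            "tracking": TrackingParams,
            "statistics": StatisticsParams,
        }
        for name, section_cls in sections.items():
            if name in data:
                kwargs[name] = _build(section_cls, data[name], name)
        if "scenes" in data:
            scenes = {}
            for sname, sdata in (data["scenes"] or {}).items():
                scenes[sname] = _build(SceneSpec, sdata, f"scenes.{sname}")
            kwargs["scenes"] = scenes
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenes"] = {
            name: dataclasses.asdict(spec) for name, spec in self.scenes.items()
        }
        return d

    def sha256(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()

    def dump(self, path: str | Path) -> None:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            if isinstance(obj, list):
                return [clean(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(clean(self.to_dict()), sort_keys=True))


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML/JSON config; ``None`` yields the defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text()) or {}
    return PipelineConfig.from_dict(data)
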