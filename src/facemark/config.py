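"""Run configuration: defaults, YAML loading, strict key checking."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .lktrack import TrackerConfig


class ConfigError(ValueError):
    pass


@dataclass
class DetectorConfig:
    backend: str = "manual"            # "manual" | "bright-region"
    box_width_factor: float = 2.5
    box_aspect: float = 1.3
    eye_level: float = 0.4


@dataclass
class GeometryConfig:
    eye_mouth_factor: float = 1.1
    axis_scale: float = 1.0
    profile_path: str | None = None    # placement-profile YAML override


@dataclass
class FeatureConfig:
    mode: str = "CMD"                  # "MD" | "CMD"
    statistic: str = "rms"             # "mean" | "rms" | "variance"
    normalization: str = "bipolar"     # "none" | "binary" | "bipolar"
    baseline_frames: int = 1
    absolute_cmd: bool = False


@dataclass
class ClassifierSection:
    kind: str = "pnn"                  # "knn" | "pnn"
    k: int = 5
    sigma: float | None = None         # None -> sweep sigma_grid
    sigma_grid: list[float] = field(
        default_factory=lambda: [round(0.01 * i, 2) for i in range(1, 11)]
    )
    n_folds: int = 10
    subject_grouped: bool = False
    seed: int = 0


@dataclass
class RunConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierSection = field(default_factory=ClassifierSection)

    def digest(self) -> str:
        """Short hash of the canonical config, for run logs."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build(cls, data: Mapping[str, Any], path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys under {path!r}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | None) -> RunConfig:
    """Load a YAML run config; missing sections fall back to defaults,
    unknown keys are rejected."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    sections = {
        "detector": DetectorConfig,
        "geometry": GeometryConfig,
        "tracker": TrackerConfig,
        "features": FeatureConfig,
        "classifier": ClassifierSection,
    }
    unknown = set(raw) - set(sections)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            try:
                kwargs[name] = _build(cls, raw[name], name)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad section {name!r}: {exc}") from exc
    return RunConfig(**kwargs)
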