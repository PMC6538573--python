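"""Pipeline configuration: YAML/JSON loading with strict key checking.

Unknown keys are rejected rather than ignored so a typo in a threshold
name cannot silently run the pipeline with defaults.  Every effective
setting is echoed into the run log; output files carry a config hash.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields as dc_fields

import yaml

from .filtering import FilterSettings
from .io_model import FormatSpec
from .processing import ProcessingSettings


class ConfigError(ValueError):
    """Malformed configuration."""


class MissingSettingError(ConfigError):
    """A required setting has no value and no silent default exists."""


@dataclass
class SegmentationSettings:
    # max_missing_pct has deliberately no default: how much missing data a
    # segment may carry is a study-level decision.
    max_missing_pct: float | None = None
    bin_ms: float = 100.0
    pairing: dict = field(default_factory=dict)

    def require_max_missing_pct(self) -> float:
        if self.max_missing_pct is None:
            raise MissingSettingError(
                "segmentation.max_missing_pct is required (no default is applied)"
            )
        return float(self.max_missing_pct)


@dataclass
class PipelineConfig:
    io: FormatSpec = field(default_factory=FormatSpec)
    filter: FilterSettings = field(default_factory=FilterSettings)
    processing: ProcessingSettings = field(default_factory=ProcessingSettings)
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    output_dir: str = "pupilprep_out"
    plots: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build(cls, data: dict, where: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where!r} block: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid {where!r} block: {e}") from e


def config_from_dict(data: dict) -> PipelineConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {"io", "filter", "processing", "segmentation", "output_dir", "plots"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    return PipelineConfig(
        io=_build(FormatSpec, data.get("io", {}) or {}, "io"),
        filter=_build(FilterSettings, data.get("filter", {}) or {}, "filter"),
        processing=_build(ProcessingSettings, data.get("processing", {}) or {}, "processing"),
        segmentation=_build(SegmentationSettings, data.get("segmentation", {}) or {}, "segmentation"),
        output_dir=str(data.get("output_dir", "pupilprep_out")),
        plots=bool(data.get("plots", True)),
    )


def load_config(path) -> PipelineConfig:
    """Load a YAML (or JSON — a YAML subset) configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse config {path}: {e}") from e
    return config_from_dict(data or {})
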