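"""Run configuration: a structured, human-readable YAML key/value file.

Every tunable of the pipeline lives here so that a run is reproducible
from its resolved configuration alone. Unknown keys are rejected rather
than ignored, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .detection import SaccadeDetectorConfig
from .diagnosis import DecisionThresholds
from .model import CalibrationConstants, ConfigError, StimulusProtocol
from .preprocessing import FilterSpec

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    filter: FilterSpec = field(default_factory=FilterSpec)
    detector: SaccadeDetectorConfig = field(default_factory=SaccadeDetectorConfig)
    thresholds: DecisionThresholds = field(default_factory=DecisionThresholds)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)
    settle_ms: float = 500.0
    delay_mode: str = "first"
    smooth: str = "off"
    smooth_window: int = 100
    seed: Optional[int] = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.delay_mode not in ("first", "mean"):
            raise ConfigError(f"delay_mode must be 'first' or 'mean', got {self.delay_mode!r}")
        if self.smooth not in ("mean", "median", "off"):
            raise ConfigError(f"smooth must be mean/median/off, got {self.smooth!r}")
        if self.smooth_window < 1:
            raise ConfigError("smooth_window must be >= 1")


_SECTIONS = {
    "filter": FilterSpec,
    "detector": SaccadeDetectorConfig,
    "thresholds": DecisionThresholds,
    "protocol": StimulusProtocol,
    "calibration": CalibrationConstants,
}

_SCALARS = {"settle_ms", "delay_mode", "smooth", "smooth_window", "seed", "verbosity"}


def _build_section(cls, mapping: dict, section: str):
    if not isinstance(mapping, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{section}': {', '.join(sorted(unknown))}"
        )
    kwargs = dict(mapping)
    # YAML lists come back as lists; protocol stores a tuple
    if "direction_change_times_s" in kwargs:
        kwargs["direction_change_times_s"] = tuple(kwargs["direction_change_times_s"])
    return cls(**kwargs)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Parse a YAML config file into a validated :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name], name)
    for name in _SCALARS:
        if name in raw:
            kwargs[name] = raw[name]
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path: Optional[Union[str, Path]] = None) -> str:
    """Serialise a config back to YAML; round-trips through :func:`load_config`."""
    doc = {
        name: dataclasses.asdict(getattr(cfg, name)) for name in _SECTIONS
    }
    doc["protocol"]["direction_change_times_s"] = list(
        doc["protocol"]["direction_change_times_s"]
    )
    doc["calibration"] = dataclasses.asdict(cfg.calibration)
    doc["filter"]["mode"] = cfg.filter.mode
    for name in _SCALARS:
        doc[name] = getattr(cfg, name)
    # enums/None serialise poorly by default; keep plain scalars
    text = yaml.safe_dump(doc, sort_keys=True, default_flow_style=False)
    if path is not None:
        Path(path).write_text(text)
    return text
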