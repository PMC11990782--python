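"""YAML configuration loading with strict validation.

A run configuration mirrors the dataclass tree of the library —
``tracker`` (with nested ``tiers``, ``noise``, ``cmc``) and ``scenario``
— plus the evaluation IoU threshold and the global seed.  Unknown keys
are rejected rather than ignored, and every dataclass's own
``__post_init__`` bounds-checks its values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, is_dataclass
from typing import Any, get_type_hints

import yaml

from .cmc import CMCParams
from .cos import TierConfig
from .kalman import NoiseConfig
from .synthetic import ScenarioConfig
from .tracker import TrackerConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config", "config_from_dict"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    """Merged configuration for simulate / track / evaluate runs."""

    seed: int = 0
    iou_min: float = 0.5
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_min <= 1.0:
            raise ConfigError(f"iou_min must be in (0, 1], got {self.iou_min}")


def _build(cls, data: dict[str, Any], path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping, got {type(data).__name__}")
    hints = get_type_hints(cls)
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"{path or cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        f = known[name]
        target = hints.get(name)
        default = (
            f.default_factory() if f.default_factory is not dataclasses.MISSING else f.default
        )
        sub = f"{path}.{name}" if path else name
        if is_dataclass(target) and isinstance(value, dict):
            kwargs[name] = _build(target, value, sub)
        elif isinstance(default, tuple) and isinstance(value, (list, tuple)):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or cls.__name__}: {exc}") from exc


def config_from_dict(data: dict[str, Any] | None) -> RunConfig:
    return _build(RunConfig, data or {}, "")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return config_from_dict(data)


def _to_plain(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def dump_config(cfg: RunConfig, path) -> None:
    """Serialise a configuration so that load(dump(cfg)) == cfg."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=True)
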