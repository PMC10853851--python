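"""Run configuration: YAML/JSON loading with strict schema validation.

The file mirrors the library's dataclasses section by section::

    cohort:
      n_participants: 30
    session:
      frequency_order: [2000, 4000, 8000, 1000, 500, 250]
    engine:
      staircase:
        start_level: 60
      hughson_westlake:
        confirmations_required: 2
    stats:
      tolerance_db: 10
      criterion_db: 20
      confidence: 0.95
    seed: 1
    output_dir: out

Every key is optional (defaults are the documented study conditions);
unknown keys are rejected with the offending dotted path in the message.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .engines import HWConfig, StaircaseConfig, TestSessionConfig
from .listeners import (
    DEFAULT_INDEX_PSYCHOMETRICS,
    DEFAULT_REFERENCE_PSYCHOMETRICS,
    CohortConfig,
    PsychometricParams,
)

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "StatsConfig", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Schema violation: names the offending key."""


@dataclass(frozen=True)
class StatsConfig:
    tolerance_db: float = 10.0
    criterion_db: float = 20.0
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.tolerance_db < 0:
            raise ValueError("tolerance_db must be >= 0")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    session: TestSessionConfig = field(default_factory=TestSessionConfig)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    hughson_westlake: HWConfig = field(default_factory=HWConfig)
    psychometrics_reference: PsychometricParams = DEFAULT_REFERENCE_PSYCHOMETRICS
    psychometrics_index: PsychometricParams = DEFAULT_INDEX_PSYCHOMETRICS
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int | None = None
    output_dir: str = "out"


def _build(cls, data: Mapping[str, Any], path: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key: {path}.{sorted(unknown)[0]}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


_SECTIONS = {
    "cohort": CohortConfig,
    "session": TestSessionConfig,
    "stats": StatsConfig,
    "psychometrics_reference": PsychometricParams,
    "psychometrics_index": PsychometricParams,
}
_ENGINE_SECTIONS = {
    "staircase": StaircaseConfig,
    "hughson_westlake": HWConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    An empty file yields all documented defaults. Unknown keys anywhere in
    the tree raise :class:`ConfigError` naming the key. The fully resolved
    configuration is echoed to the module logger.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else None
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("top level must be a mapping")

    allowed = set(_SECTIONS) | {"engine", "seed", "output_dir"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown key: {sorted(unknown)[0]}")

    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name], name)

    engine = raw.get("engine", {})
    if not isinstance(engine, Mapping):
        raise ConfigError("engine: expected a mapping")
    unknown = set(engine) - set(_ENGINE_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown key: engine.{sorted(unknown)[0]}")
    for name, cls in _ENGINE_SECTIONS.items():
        if name in engine:
            kwargs[name] = _build(cls, engine[name], f"engine.{name}")

    if "seed" in raw:
        seed = raw["seed"]
        if seed is not None and not isinstance(seed, int):
            raise ConfigError("seed: expected an integer")
        kwargs["seed"] = seed
    if "output_dir" in raw:
        if not isinstance(raw["output_dir"], str):
            raise ConfigError("output_dir: expected a string")
        kwargs["output_dir"] = raw["output_dir"]

    config = RunConfig(**kwargs)
    logger.info("resolved configuration: %s", config)
    return config


def dump_config(config: RunConfig) -> str:
    """Serialize a resolved RunConfig back to YAML (for run logs)."""
    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        return obj

    doc = plain(config)
    doc["engine"] = {
        "staircase": doc.pop("staircase"),
        "hughson_westlake": doc.pop("hughson_westlake"),
    }
    return yaml.safe_dump(doc, sort_keys=False)
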