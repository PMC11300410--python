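"""Run configuration: tie policy, utility mode, aggregation, scale-mapping
overrides, output format, and the seed used by the synthetic generator."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .scales import ScaleMapping
from .utility import TIE_POLICIES, UTILITY_MODES

__all__ = ["RunConfig", "ConfigError"]

_AGGREGATIONS = ("weighted", "unweighted")
_OUTPUT_FORMATS = ("markdown", "json")


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-enumeration values."""


@dataclass(frozen=True)
class RunConfig:
    tie_policy: str = "midrank"
    utility_mode: str = "anchored"
    aggregation: str = "weighted"
    mapping: ScaleMapping = field(default_factory=ScaleMapping)
    output_format: str = "markdown"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tie_policy not in TIE_POLICIES:
            raise ConfigError(f"tie_policy must be one of {TIE_POLICIES}")
        if self.utility_mode not in UTILITY_MODES:
            raise ConfigError(f"utility_mode must be one of {UTILITY_MODES}")
        if self.aggregation not in _AGGREGATIONS:
            raise ConfigError(f"aggregation must be one of {_AGGREGATIONS}")
        if self.output_format not in _OUTPUT_FORMATS:
            raise ConfigError(f"output_format must be one of {_OUTPUT_FORMATS}")

    def to_dict(self) -> dict:
        return {
            "tie_policy": self.tie_policy,
            "utility_mode": self.utility_mode,
            "aggregation": self.aggregation,
            "scale_mapping": self.mapping.to_dict(),
            "output_format": self.output_format,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {
            "tie_policy", "utility_mode", "aggregation", "scale_mapping",
            "output_format", "seed",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        mapping = ScaleMapping.from_dict(data.get("scale_mapping", {}))
        return cls(
            tie_policy=data.get("tie_policy", "midrank"),
            utility_mode=data.get("utility_mode", "anchored"),
            aggregation=data.get("aggregation", "weighted"),
            mapping=mapping,
            output_format=data.get("output_format", "markdown"),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)
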