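"""Structured run configuration: one section per stage, YAML round-trip,
unknown keys rejected, defaults matching the pipeline's published constants
(4.0 A contact cutoff; top 20 poses; -8.0 kcal/mol; 3.0 A; 150/130 A^2; 4 ps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .contacts import ContactConfig
from .permeability import PermeabilityConfig
from .posefilter import FilterConfig
from .stability import StabilityConfig

__all__ = ["GlobalConfig", "OccupancyConfig", "RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class GlobalConfig:
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "pepscreen_out"


@dataclass
class OccupancyConfig:
    spacing: float = 1.0
    margin: float = 8.0
    window: float = 0.5
    report_radius: float = 5.0
    min_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")


@dataclass
class RunConfig:
    global_: GlobalConfig = field(default_factory=GlobalConfig)
    contacts: ContactConfig = field(default_factory=ContactConfig)
    posefilter: FilterConfig = field(default_factory=FilterConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    permeability: PermeabilityConfig = field(default_factory=PermeabilityConfig)
    occupancy: OccupancyConfig = field(default_factory=OccupancyConfig)

    _SECTIONS = {
        "global": ("global_", GlobalConfig),
        "contacts": ("contacts", ContactConfig),
        "posefilter": ("posefilter", FilterConfig),
        "stability": ("stability", StabilityConfig),
        "permeability": ("permeability", PermeabilityConfig),
        "occupancy": ("occupancy", OccupancyConfig),
    }

    def to_dict(self) -> dict:
        out = {}
        for section, (attr, _cls) in self._SECTIONS.items():
            out[section] = dataclasses.asdict(getattr(self, attr))
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(cls._SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for section, payload in data.items():
            attr, section_cls = cls._SECTIONS[section]
            valid = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(payload or {}) - valid
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
            kwargs[attr] = section_cls(**(payload or {}))
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
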