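"""Run configuration: serialisable settings with protocol defaults.

Every default equals the reference experimental configuration: 20 charge
levels from 3 to 31.5 nC, 32 repetitions at 4 Hz; evoked window [9, 45) ms
and spontaneous window [150, 250) ms; three-SD significance criterion;
25 µA current quantisation.  Configs round-trip through YAML and hash
stably so every pipeline output can record the exact settings it was
produced under.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pulses import PROTOCOL_SHAPES, parse_shape_label
from .simulate import DEFAULT_EFFECTS, GroundTruthPrior, ShapeEffect

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


DEFAULT_SHAPES = ("Rec-C", "FS85-C", "FS80-C", "FA750-C", "FA500-C")


@dataclass
class ScheduleConfig:
    min_nC: float = 3.0
    max_nC: float = 31.5
    n_levels: int = 20
    n_repetitions: int = 32
    rate_Hz: float = 4.0


@dataclass
class WindowConfig:
    evoked_ms: tuple[float, float] = (9.0, 45.0)
    spont_ms: tuple[float, float] = (150.0, 250.0)


@dataclass
class QuantizationConfig:
    current_step_uA: float = 25.0
    min_dwell_us: float = 3.5
    sample_period_us: float = 1.0
    enabled: bool = True


@dataclass
class SimulationConfig:
    n_recordings: int = 106
    prior: GroundTruthPrior = field(default_factory=GroundTruthPrior)
    effects_by_shape: dict[str, ShapeEffect] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    trial_order: str = "blocks"


@dataclass
class RunConfig:
    """Full pipeline configuration (simulate -> quantify -> compare)."""

    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    shapes: tuple[str, ...] = DEFAULT_SHAPES
    ref_shape: str = "Rec-C"
    windows: WindowConfig = field(default_factory=WindowConfig)
    sd_multiplier: float = 3.0
    quantization: QuantizationConfig = field(default_factory=QuantizationConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    output_dir: str = "rampulse_out"

    def __post_init__(self) -> None:
        for label in (*self.shapes, self.ref_shape):
            try:
                parse_shape_label(label)
            except Exception as exc:
                raise ConfigError(f"shapes/ref_shape: unknown shape id {label!r}") from exc
        if self.ref_shape not in self.shapes:
            raise ConfigError(f"ref_shape {self.ref_shape!r} must appear in shapes")
        for label in self.simulation.effects_by_shape:
            if label not in PROTOCOL_SHAPES:
                raise ConfigError(
                    f"simulation.effects_by_shape: unknown shape stem {label!r}"
                )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "schedule" in d:
            d["schedule"] = ScheduleConfig(**d["schedule"])
        if "windows" in d:
            w = d["windows"]
            d["windows"] = WindowConfig(
                evoked_ms=tuple(w["evoked_ms"]), spont_ms=tuple(w["spont_ms"])
            )
        if "quantization" in d:
            d["quantization"] = QuantizationConfig(**d["quantization"])
        if "simulation" in d:
            s = dict(d["simulation"])
            if "prior" in s:
                p = {
                    k: tuple(v) if isinstance(v, (list, tuple)) else v
                    for k, v in s["prior"].items()
                }
                s["prior"] = GroundTruthPrior(**p)
            if "effects_by_shape" in s:
                s["effects_by_shape"] = {
                    k: v if isinstance(v, ShapeEffect) else ShapeEffect(**v)
                    for k, v in s["effects_by_shape"].items()
                }
            d["simulation"] = SimulationConfig(**s)
        if "shapes" in d:
            d["shapes"] = tuple(d["shapes"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable short hash of the canonicalised configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
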