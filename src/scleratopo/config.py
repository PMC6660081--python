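"""Pipeline configuration: defaults, file loading, validation, hashing.

Defaults match the method's stated values where given: 0.1 mm / 11
element moving window, tripled-mean cut-off threshold, one-degree
meridians, 8 mm sampling radius, 11.5 mm reference sphere.  Unknown keys
are rejected, and every output file carries the SHA-256 hash of the
canonical config JSON for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class LimbusSection:
    search_window_mm: tuple[float, float] = (3.5, 7.0)
    smooth_sigma_mm: float = 0.3
    min_prominence: float = 0.1


@dataclass
class WindowSection:
    halfwidth_mm: float = 0.1
    max_elements: int = 11
    statistic: str = "median"


@dataclass
class ThresholdSection:
    factor: float = 3.0
    baseline: str = "post_limbus"  # or "full"


@dataclass
class EdgeSection:
    search_offset_mm: float = 0.25
    min_prominence_um: float = 20.0
    second_edge_ordering: str = "radius"  # or "value"


@dataclass
class SphereSection:
    objective: str = "algebraic"  # or "geometric"
    annulus_offset_mm: float = 0.25


@dataclass
class TTestSection:
    variant: str = "welch"  # or "pooled"


@dataclass
class PipelineConfig:
    angular_step_deg: float = 1.0
    radial_step_mm: float = 0.05
    sampling_radius_mm: float = 8.0
    reference_radius_mm: float = 11.5
    io_dialect: str = "xyz-csv"  # or "mat-container"
    mat_variables: dict = field(default_factory=lambda: {"x": "x", "y": "y", "z": "z"})
    limbus: LimbusSection = field(default_factory=LimbusSection)
    window: WindowSection = field(default_factory=WindowSection)
    threshold: ThresholdSection = field(default_factory=ThresholdSection)
    edge: EdgeSection = field(default_factory=EdgeSection)
    sphere: SphereSection = field(default_factory=SphereSection)
    ttest: TTestSection = field(default_factory=TTestSection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, path="")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config root must be a mapping")
        return cls.from_dict(data)


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = path or "config"
        raise ConfigurationError(f"unknown key(s) in {where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        sub = _SECTION_TYPES.get(name)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, path=f"{path}.{name}" if path else name)
        elif name == "search_window_mm" and isinstance(value, (list, tuple)):
            kwargs[name] = tuple(float(v) for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SECTION_TYPES = {
    "limbus": LimbusSection,
    "window": WindowSection,
    "threshold": ThresholdSection,
    "edge": EdgeSection,
    "sphere": SphereSection,
    "ttest": TTestSection,
}
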