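"""Pipeline configuration: strict schema, YAML/JSON loading, hashing.

Unknown keys are rejected by name at every nesting level; defaults match
the per-module documented values exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = [
    "PipelineConfig",
    "SimulateConfig",
    "GroupSpec",
    "BiomechBlock",
    "DensitometryBlock",
    "KSBlock",
    "ConfigError",
    "load_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Raised on unknown keys or invalid configuration values."""


def _from_dict(cls, data: dict, path: str = ""):
    """Instantiate a (possibly nested) dataclass, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping at {path or 'top level'}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}"
        )
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        sub = _NESTED.get((cls, name))
        if sub is not None and value is not None:
            if isinstance(sub, tuple):  # list of dataclasses
                (elem,) = sub
                kwargs[name] = tuple(
                    _from_dict(elem, v, f"{path}{name}[{i}].")
                    for i, v in enumerate(value)
                )
            else:
                kwargs[name] = _from_dict(sub, value, f"{path}{name}.")
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config at {path or 'top level'}: {exc}") from exc


@dataclass(frozen=True)
class GroupSpec:
    """One mutant group to simulate and score."""

    name: str
    deficit_sd: float
    n: int = 8


@dataclass(frozen=True)
class SimulateConfig:
    cohort_n: int = 320
    bmc_mean: float = 100.0
    bmc_cv: float = 0.02
    bmc_correlation: float = 0.6
    groups: tuple[GroupSpec, ...] = (
        GroupSpec(name="het", deficit_sd=-1.0),
        GroupSpec(name="hom", deficit_sd=-2.5),
    )
    n_curves: int = 12
    curve_noise_sd: float = 0.05
    gray_field_size: tuple[int, int] = (96, 96)
    bone_density_mean: float = 1200.0
    bone_density_sd: float = 100.0
    mutant_density_shift: float = -0.05  # fractional shift of the bone mean
    n_histomorph_sections: int = 2


@dataclass(frozen=True)
class BiomechBlock:
    contact_fraction: float = 0.01
    min_window_fraction: float = 0.10
    r2_min: float = 0.995
    yield_offset_fraction: float = 0.02
    fracture_drop_fraction: float = 0.30
    smooth_window: Optional[int] = None


@dataclass(frozen=True)
class DensitometryBlock:
    n_bins_bmc: int = 16
    n_bins_qbse: int = 8
    standards: tuple[tuple[str, float], ...] = (
        ("polyester", 400.0),
        ("aluminum", 1800.0),
    )


@dataclass(frozen=True)
class KSBlock:
    alpha_levels: tuple[float, ...] = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class PipelineConfig:
    schema_version: int = 1
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    biomech: BiomechBlock = field(default_factory=BiomechBlock)
    densitometry: DensitometryBlock = field(default_factory=DensitometryBlock)
    ks: KSBlock = field(default_factory=KSBlock)

    def __post_init__(self) -> None:
        if self.schema_version != 1:
            raise ConfigError(f"unsupported schema_version {self.schema_version}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_NESTED: dict[tuple[type, str], Any] = {
    (PipelineConfig, "simulate"): SimulateConfig,
    (PipelineConfig, "biomech"): BiomechBlock,
    (PipelineConfig, "densitometry"): DensitometryBlock,
    (PipelineConfig, "ks"): KSBlock,
    (SimulateConfig, "groups"): (GroupSpec,),
}


def load_config(path: Optional[Path]) -> PipelineConfig:
    """Load a YAML or JSON config file; None gives all defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.from_dict(data)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full (defaults-expanded) configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
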