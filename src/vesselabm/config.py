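"""Simulation configuration: nested parameter dataclasses plus YAML I/O.

A :class:`SimulationConfig` gathers every model constant — geometry,
clocks, damage model, biochemical factor kinetics, event-probability
coefficients, the WSS source, and run bookkeeping. Configs load from and
save to YAML; unknown keys are rejected so typos fail loudly, and every
nested dataclass revalidates its own invariants on construction.

The shipped default configuration (``data/default_config.yaml``) carries
the frozen calibrated probability coefficients and the reference low-WSS
sector profile used for reproduction runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .biochem import (
    ConversionParams,
    ETParams,
    MMP9Params,
    NOParams,
    ProbabilityParams,
)
from .core import ClockSpec, GeometrySpec, RemodelingState
from .damage import DamageParams

__all__ = [
    "BiochemConfig",
    "WSSSourceConfig",
    "SimulationConfig",
    "load_config",
    "save_config",
    "default_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Raised for malformed or invalid configuration input."""


@dataclass(frozen=True)
class BiochemConfig:
    """Grouped biochemical parameters plus the virtual-EC density."""

    et: ETParams = ETParams()
    no: NOParams = NOParams()
    mmp9: MMP9Params = MMP9Params()
    conversion: ConversionParams = ConversionParams()
    n_ec_per_site: float = 1.0

    def __post_init__(self) -> None:
        if self.n_ec_per_site < 0:
            raise ConfigError("n_ec_per_site must be non-negative")


@dataclass(frozen=True)
class WSSSourceConfig:
    """Where the angular WSS profile comes from.

    ``type`` is one of ``"poiseuille"`` (uniform analytic level from tube
    parameters), ``"sector"`` (parametric low-WSS sector) or ``"csv"``
    (imported profile). Only the fields of the active type are used.
    """

    type: str = "sector"
    # sector parameters
    tau_base: float = 1.2
    tau_min: float = 0.1
    center_deg: float = 90.0
    width_deg: float = 120.0
    n_samples: int = 360
    # poiseuille parameters
    radius_m: float = 1.535e-3
    viscosity_pa_s: float = 3.5e-3
    density_kg_m3: float = 1060.0
    flow_ml_min: float = 50.0
    # csv source
    path: str | None = None

    def __post_init__(self) -> None:
        if self.type not in ("poiseuille", "sector", "csv"):
            raise ConfigError(f"unknown wss_source type {self.type!r}")
        if self.type == "csv" and not self.path:
            raise ConfigError("wss_source type 'csv' requires a path")


@dataclass(frozen=True)
class SimulationConfig:
    geometry: GeometrySpec = GeometrySpec()
    clocks: ClockSpec = ClockSpec()
    damage: DamageParams = DamageParams()
    biochem: BiochemConfig = BiochemConfig()
    probabilities: ProbabilityParams = ProbabilityParams()
    burden_threshold: float = 0.40
    vsmc_fraction: float = 0.5
    wss_source: WSSSourceConfig = WSSSourceConfig()
    seed: int = 1
    snapshot_every: int = 100
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.burden_threshold < 1:
            raise ConfigError("burden_threshold must lie in (0, 1)")
        if not 0 <= self.vsmc_fraction <= 1:
            raise ConfigError("vsmc_fraction must lie in [0, 1]")
        if self.snapshot_every <= 0:
            raise ConfigError("snapshot_every must be positive")

    def remodeling_state(self) -> RemodelingState:
        return RemodelingState(burden_threshold=self.burden_threshold)


_NESTED = {
    "geometry": GeometrySpec,
    "clocks": ClockSpec,
    "damage": DamageParams,
    "biochem": BiochemConfig,
    "probabilities": ProbabilityParams,
    "wss_source": WSSSourceConfig,
}
_BIOCHEM_NESTED = {
    "et": ETParams,
    "no": NOParams,
    "mmp9": MMP9Params,
    "conversion": ConversionParams,
}


def _build(cls, data, context: str):
    """Construct dataclass ``cls`` from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        sub = None
        if cls is SimulationConfig:
            sub = _NESTED.get(key)
        elif cls is BiochemConfig:
            sub = _BIOCHEM_NESTED.get(key)
        if sub is not None:
            kwargs[key] = _build(sub, value, f"{context}.{key}")
        elif key == "center":
            kwargs[key] = tuple(value)
        elif key == "printed_constants":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return _build(SimulationConfig, data, context=str(path))


def save_config(config: SimulationConfig, path) -> None:
    """Write a configuration as YAML (round-trips through load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False)


def default_config() -> SimulationConfig:
    """The shipped default configuration with frozen calibrated parameters."""
    ref = resources.files("vesselabm").joinpath("data/default_config.yaml")
    with resources.as_file(ref) as path:
        return load_config(path)


def config_hash(config: SimulationConfig) -> str:
    """Short stable hash of a configuration, for run provenance logging."""
    payload = json.dumps(_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
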