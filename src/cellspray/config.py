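"""Run configuration: defaults, YAML merging, unit parsing.

Everything is SI internally; the CLI and config files accept the units
practitioners use at the rig (um for droplet sizes, mPa s for viscosities,
multiples of 1e5 Pa for the atomizing pressure) and convert on ingest.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Any

import yaml

from .imaging import ImagingSetup
from .impact import (
    CellProperties,
    FluidProperties,
    ModelConstants,
    SubstrateProperties,
    SurvivalParameters,
)
from .synth import SprayGeneratorConfig

__all__ = [
    "RunConfig",
    "parse_length",
    "parse_velocity",
    "parse_viscosity",
    "parse_pressure",
]

_NUM = r"([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)"

_LENGTH_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9, "cm": 1e-2}
_VISCOSITY_UNITS = {"pas": 1.0, "pa.s": 1.0, "mpas": 1e-3, "mpa.s": 1e-3, "cp": 1e-3}
_PRESSURE_UNITS = {"pa": 1.0, "kpa": 1e3, "bar": 1e5, "": 1e5}
_VELOCITY_UNITS = {"m/s": 1.0, "ms": 1.0, "mps": 1.0, "": 1.0}


def _parse(value: str | float, units: dict[str, float], default_unit: str,
           kind: str) -> float:
    if isinstance(value, (int, float)):
        return float(value) * units[default_unit]
    m = re.fullmatch(_NUM + r"\s*([a-zA-Zµ/.]*)", value.strip())
    if not m:
        raise ValueError(f"cannot parse {kind} {value!r}")
    number, unit = float(m.group(1)), m.group(2).strip().lower()
    if unit == "":
        unit = default_unit
    # length units are case-normalized already; viscosity keys are lowercase
    key = unit if unit in units else unit.lower()
    if key not in units:
        raise ValueError(f"unknown {kind} unit {m.group(2)!r} in {value!r}; "
                         f"accepted: {sorted(units)}")
    return number * units[key]


def parse_length(value: str | float, default_unit: str = "m") -> float:
    """``"39um"`` -> 3.9e-5; bare numbers are metres by default."""
    return _parse(value, _LENGTH_UNITS, default_unit, "length")


def parse_velocity(value: str | float) -> float:
    """Velocities in m/s; bare numbers pass through."""
    return _parse(value, _VELOCITY_UNITS, "", "velocity")


def parse_viscosity(value: str | float, default_unit: str = "pas") -> float:
    """``"1mPas"`` -> 1e-3 Pa s; bare numbers are Pa s by default."""
    return _parse(value, _VISCOSITY_UNITS, default_unit, "viscosity")


def parse_pressure(value: str | float) -> float:
    """Pressures; bare numbers are in units of 1e5 Pa (the gauge scale of
    spray rigs), so ``0.4`` -> 4e4 Pa; ``"40kPa"`` and ``"0.4bar"`` work too."""
    return _parse(value, _PRESSURE_UNITS, "", "pressure")


def _build(cls, base, overrides: dict[str, Any] | None, caster=None):
    if not overrides:
        return base
    kwargs = dataclasses.asdict(base)
    for key, value in overrides.items():
        if key not in kwargs:
            raise ValueError(f"unknown {cls.__name__} field {key!r}")
        kwargs[key] = caster(key, value) if caster else value
    return cls(**kwargs)


def _cast_cell(key: str, value):
    if key == "diameter":
        return parse_length(value, "um") if isinstance(value, str) else float(value)
    if key == "viscosity":
        return parse_viscosity(value)
    return float(value)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run settings, serialized next to every output."""

    cell: CellProperties = CellProperties()
    fluid: FluidProperties = FluidProperties()
    substrate: SubstrateProperties = SubstrateProperties.hard()
    survival: SurvivalParameters = SurvivalParameters()
    constants: ModelConstants = ModelConstants()
    generator: SprayGeneratorConfig = SprayGeneratorConfig()
    imaging: ImagingSetup = ImagingSetup()
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data or {})
        constants = _build(ModelConstants, ModelConstants(), data.pop("constants", None))
        sub_spec = data.pop("substrate", None) or {}
        if "gelatin_fraction" in sub_spec and sub_spec.get("stiffness") is None:
            substrate = SubstrateProperties.from_gelatin(
                float(sub_spec["gelatin_fraction"]), constants)
        elif sub_spec:
            substrate = SubstrateProperties(**{k: v for k, v in sub_spec.items()})
        else:
            substrate = SubstrateProperties.hard()
        cfg = cls(
            cell=_build(CellProperties, CellProperties(), data.pop("cell", None), _cast_cell),
            fluid=_build(FluidProperties, FluidProperties(), data.pop("fluid", None), _cast_cell),
            substrate=substrate,
            survival=_build(SurvivalParameters, SurvivalParameters(), data.pop("survival", None)),
            constants=constants,
            generator=_build(SprayGeneratorConfig, SprayGeneratorConfig(),
                             data.pop("generator", None)),
            imaging=_build(ImagingSetup, ImagingSetup(), data.pop("imaging", None)),
            seed=int(data.pop("seed", 0)),
            verbosity=int(data.pop("verbosity", 0)),
        )
        if data:
            raise ValueError(f"unknown config sections: {sorted(data)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
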