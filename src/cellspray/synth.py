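"""Seeded generator of synthetic spray spectra.

Real spray spectra from two-phase nozzles are right-skewed in diameter and
broad in velocity; raising the atomizing air pressure shrinks the droplets
and speeds them up, while a longer flight distance to the substrate slows
them down through air drag.  This module draws (diameter, velocity) samples
with exactly that structure so the ensemble and sweep machinery can run
without measured spectra.  The distribution family and coefficients are
synthetic stand-ins chosen to land in the regime of clinical two-phase
spray nozzles (droplets of tens of um, impact speeds up to tens of m/s);
any measured table can replace them via
:func:`cellspray.ensemble.read_droplet_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ensemble import SpraySample

__all__ = [
    "SprayGeneratorConfig",
    "generate",
    "preset",
    "PRESET_NAMES",
    "PRESSURE_SERIES",
    "DISTANCE_SERIES",
    "GELATIN_SERIES",
]

#: Atomizing pressures (Pa) and nozzle distances (m) of the standard spray
#: parameter study, and the gelatin mass-fraction series for the substrate
#: sweep (liquid limit plus four gel fractions).
PRESSURE_SERIES = (0.2e5, 0.4e5, 0.6e5, 0.8e5, 1.0e5)
DISTANCE_SERIES = (0.030, 0.050, 0.100, 0.150)
GELATIN_SERIES = (0.0, 0.02, 0.05, 0.10, 0.20)

_REFERENCE_PRESSURE = 0.4e5  # Pa


@dataclass(frozen=True)
class SprayGeneratorConfig:
    """Parameters of the synthetic spray-spectrum generator.

    pressure, nozzle_distance, viscosity : the physical spray setting this
        spectrum emulates (Pa, m, Pa s).
    median_diameter_ref : lognormal median diameter at the reference
        pressure (m); the median scales as (P_ref/P)^pressure_size_exponent.
    sigma_log : lognormal shape parameter of the diameter distribution.
    velocity_coeff, velocity_pressure_exponent : impact speed scale,
        V ~ coeff * (P / 1e5 Pa)^exponent (m/s).
    velocity_decay_length : e-folding length of the velocity decay with
        nozzle distance (m), emulating air drag.
    velocity_noise : relative Gaussian scatter of individual velocities.
    size_velocity_exponent : velocity ~ (D/D_median)^exponent; positive
        because small droplets decelerate faster in air and arrive slower.
    seed : generator seed; identical seeds give identical samples.
    """

    pressure: float = _REFERENCE_PRESSURE
    nozzle_distance: float = 0.030
    viscosity: float = 1e-3
    median_diameter_ref: float = 30e-6
    pressure_size_exponent: float = 0.5
    sigma_log: float = 0.45
    velocity_coeff: float = 32.0
    velocity_pressure_exponent: float = 0.75
    velocity_decay_length: float = 0.10
    velocity_noise: float = 0.25
    size_velocity_exponent: float = 0.2
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.pressure <= 0:
            raise ValueError("pressure must be positive")
        if self.nozzle_distance <= 0:
            raise ValueError("nozzle distance must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.sigma_log <= 0:
            raise ValueError("diameter dispersion must be positive")
        if self.median_diameter_ref <= 0 or self.velocity_coeff <= 0:
            raise ValueError("scale parameters must be positive")
        if self.velocity_decay_length <= 0:
            raise ValueError("velocity decay length must be positive")
        if self.velocity_noise < 0:
            raise ValueError("velocity noise must be non-negative")

    @property
    def median_diameter(self) -> float:
        """Median droplet diameter at this pressure (m)."""
        return self.median_diameter_ref * (
            _REFERENCE_PRESSURE / self.pressure) ** self.pressure_size_exponent

    @property
    def mean_velocity(self) -> float:
        """Noise-free impact velocity of a median-size droplet (m/s)."""
        return (self.velocity_coeff
                * (self.pressure / 1e5) ** self.velocity_pressure_exponent
                * np.exp(-self.nozzle_distance / self.velocity_decay_length))


_PRESETS: dict[str, SprayGeneratorConfig] = {
    "reference": SprayGeneratorConfig(pressure=0.4e5, nozzle_distance=0.030,
                                      viscosity=1e-3, label="reference"),
}


def preset(name: str) -> SprayGeneratorConfig:
    """Named spray setting; ``"reference"`` is P = 0.4e5 Pa, h = 30 mm,
    mu = 1 mPa s."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise LookupError(
            f"unknown spray preset {name!r}; valid presets: {sorted(_PRESETS)}"
        ) from None


PRESET_NAMES = tuple(sorted(_PRESETS))


def generate(config: SprayGeneratorConfig, n: int,
             rng: np.random.Generator | None = None) -> SpraySample:
    """Draw ``n`` droplets from the configured synthetic spectrum.

    Diameters follow a lognormal law (clipped to the detectable 1-100 um
    range); velocities follow the pressure/distance law with a weak
    size-velocity coupling and multiplicative Gaussian noise, floored at 0.
    """
    if n < 1:
        raise ValueError("need at least one droplet")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = np.exp(rng.normal(np.log(config.median_diameter), config.sigma_log, size=n))
    d = np.clip(d, 1e-6, 100e-6)
    base_v = config.mean_velocity * (d / config.median_diameter) ** config.size_velocity_exponent
    v = base_v * (1.0 + rng.normal(0.0, config.velocity_noise, size=n))
    v = np.maximum(v, 0.0)
    meta = {"pressure": config.pressure, "distance": config.nozzle_distance,
            "viscosity": config.viscosity,
            "label": config.label or f"synthetic P={config.pressure:g} h={config.nozzle_distance:g}"}
    return SpraySample.from_arrays(d, v, metadata=meta)
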