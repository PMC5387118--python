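"""Spray-ensemble viability: from a polydisperse droplet spectrum to a
distribution of per-droplet survival probabilities and one expected
post-spray viability, plus viability maps over (diameter, velocity).
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .impact import (
    CellProperties,
    FluidProperties,
    ModelConstants,
    SubstrateProperties,
    SurvivalParameters,
    predict_eta,
)

__all__ = [
    "DropletObservation",
    "SpraySample",
    "ViabilityDistribution",
    "predict_ensemble",
    "viability_map",
    "viability_contour",
    "parameter_sweep",
    "read_droplet_table",
    "write_droplet_table",
]


@dataclass(frozen=True)
class DropletObservation:
    """One droplet: diameter (m), impact velocity (m/s), relative weight."""

    d0: float
    v0: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("droplet diameter must be positive")
        if self.v0 < 0:
            raise ValueError("droplet velocity must be non-negative")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass(frozen=True)
class SpraySample:
    """A weighted collection of droplet observations with spray metadata.

    Metadata keys in use: ``pressure`` (Pa), ``distance`` (m, nozzle to
    substrate), ``viscosity`` (Pa s), ``label``.
    """

    observations: tuple[DropletObservation, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.observations) == 0:
            raise ValueError("a spray sample needs at least one droplet")
        if sum(o.weight for o in self.observations) <= 0:
            raise ValueError("total observation weight must be positive")
        object.__setattr__(self, "observations", tuple(self.observations))

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def diameters(self) -> np.ndarray:
        return np.array([o.d0 for o in self.observations])

    @property
    def velocities(self) -> np.ndarray:
        return np.array([o.v0 for o in self.observations])

    @property
    def weights(self) -> np.ndarray:
        return np.array([o.weight for o in self.observations])

    @classmethod
    def from_arrays(cls, d0, v0, weight=None, metadata: dict | None = None) -> "SpraySample":
        d0 = np.asarray(d0, dtype=float)
        v0 = np.asarray(v0, dtype=float)
        w = np.ones_like(d0) if weight is None else np.asarray(weight, dtype=float)
        obs = tuple(DropletObservation(float(d), float(v), float(ww))
                    for d, v, ww in zip(d0, v0, w, strict=True))
        return cls(obs, dict(metadata or {}))


@dataclass(frozen=True)
class ViabilityDistribution:
    """Per-droplet survival probabilities, their histogram, and the
    weight-averaged expected post-spray viability.

    ``excluded_fraction`` is the weight fraction of droplets smaller than
    the cell, which cannot carry a cell and are left out of the average
    under the default policy.
    """

    per_droplet_eta: np.ndarray
    weights: np.ndarray
    bin_edges: np.ndarray
    bin_frequencies: np.ndarray
    mean_eta: float
    excluded_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_eta <= 1.0:
            raise ValueError("mean viability must lie in [0, 1]")


def predict_ensemble(sample: SpraySample,
                     cell: CellProperties = CellProperties(),
                     fluid: FluidProperties = FluidProperties(),
                     substrate: SubstrateProperties = SubstrateProperties.hard(),
                     params: SurvivalParameters = SurvivalParameters(),
                     constants: ModelConstants = ModelConstants(),
                     bins: int = 20,
                     small_droplet_policy: str = "exclude") -> ViabilityDistribution:
    """Survival probability of every droplet in the spray and their
    weighted average, the expected post-spray viability.

    Droplets smaller than the cell cannot contain one; the default policy
    excludes them from the average (the excluded weight fraction is
    reported), ``small_droplet_policy="bare_cell"`` instead treats them as a
    bare-cell impact (droplet diameter floored at the cell diameter).
    """
    if small_droplet_policy not in ("exclude", "bare_cell"):
        raise ValueError("small_droplet_policy must be 'exclude' or 'bare_cell'")
    d0 = sample.diameters
    v0 = sample.velocities
    w = sample.weights
    total_w = w.sum()

    small = d0 < cell.diameter
    excluded = 0.0
    if small_droplet_policy == "exclude":
        if small.all():
            raise ValueError("every droplet is smaller than the cell; nothing to average")
        excluded = float(w[small].sum() / total_w)
        d0, v0, w = d0[~small], v0[~small], w[~small]
    else:
        d0 = np.maximum(d0, cell.diameter)

    eta = predict_eta(d0, v0, cell, fluid, substrate, params, constants)
    mean = float(np.average(eta, weights=w))
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist, _ = np.histogram(eta, bins=edges, weights=w)
    freq = hist / w.sum()
    return ViabilityDistribution(
        per_droplet_eta=eta, weights=w, bin_edges=edges, bin_frequencies=freq,
        mean_eta=mean, excluded_fraction=excluded)


def viability_map(d_grid, v_grid,
                  cell: CellProperties = CellProperties(),
                  fluid: FluidProperties = FluidProperties(),
                  substrate: SubstrateProperties = SubstrateProperties.hard(),
                  params: SurvivalParameters = SurvivalParameters(),
                  constants: ModelConstants = ModelConstants()) -> np.ndarray:
    """Matrix of survival probabilities over a (diameter, velocity) grid;
    rows follow ``d_grid``, columns follow ``v_grid`` (both ascending).

    Grid diameters below the cell diameter are evaluated as bare-cell
    impacts (floored at the cell diameter) so the map covers the full
    detectable droplet range.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    v_grid = np.asarray(v_grid, dtype=float)
    for g, name in ((d_grid, "diameter"), (v_grid, "velocity")):
        if g.ndim != 1 or np.any(np.diff(g) < 0):
            raise ValueError(f"{name} grid must be 1-D and sorted ascending")
    dd = np.maximum(d_grid, cell.diameter)[:, None]
    vv = v_grid[None, :]
    return predict_eta(np.broadcast_to(dd, (d_grid.size, v_grid.size)),
                       np.broadcast_to(vv, (d_grid.size, v_grid.size)),
                       cell, fluid, substrate, params, constants)


def viability_contour(eta: np.ndarray, d_grid, v_grid, level: float = 0.5) -> np.ndarray:
    """Velocity at which each row of a viability map crosses ``level``.

    Rows of the map are non-increasing in velocity, so the crossing is
    unique; rows that never cross return NaN.  Linear interpolation between
    grid points.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    out = np.full(eta.shape[0], np.nan)
    for i, row in enumerate(eta):
        below = np.nonzero(row <= level)[0]
        if below.size == 0 or below[0] == 0:
            continue
        j = below[0]
        e0, e1 = row[j - 1], row[j]
        if e0 == e1:
            out[i] = v_grid[j]
        else:
            out[i] = v_grid[j - 1] + (e0 - level) / (e0 - e1) * (v_grid[j] - v_grid[j - 1])
    return out


_SWEEP_PARAMETERS = ("pressure", "distance", "viscosity", "gelatin")


def parameter_sweep(parameter: str,
                    values: Sequence[float],
                    samples: Sequence[SpraySample] | None = None,
                    sample_factory: Callable[[float], SpraySample] | None = None,
                    cell: CellProperties = CellProperties(),
                    fluid: FluidProperties = FluidProperties(),
                    substrate: SubstrateProperties = SubstrateProperties.hard(),
                    params: SurvivalParameters = SurvivalParameters(),
                    constants: ModelConstants = ModelConstants(),
                    **ensemble_kwargs) -> pd.DataFrame:
    """Expected viability as one spray parameter varies.

    For ``pressure`` and ``distance`` the droplet spectrum itself changes,
    so one :class:`SpraySample` per value must be supplied (measured tables
    or synthetic spectra), either directly via ``samples`` or through
    ``sample_factory(value)``.  For ``viscosity`` and ``gelatin`` a single
    sample may be given: the spectrum is fixed and the model inputs (bio-ink
    viscosity, substrate stiffness) change instead.
    """
    if parameter not in _SWEEP_PARAMETERS:
        raise ValueError(f"unknown sweep parameter {parameter!r}; choose from {_SWEEP_PARAMETERS}")
    values = list(values)
    if samples is not None and len(samples) == 1 and parameter in ("viscosity", "gelatin"):
        samples = list(samples) * len(values)
    if samples is None:
        if sample_factory is None:
            raise ValueError("provide a SpraySample per grid point (samples=...) "
                             "or a sample_factory")
        samples = [sample_factory(v) for v in values]
    if len(samples) != len(values):
        raise ValueError(f"{len(values)} sweep values but {len(samples)} samples")

    rows = []
    for value, sample in zip(values, samples):
        flu, sub = fluid, substrate
        if parameter == "viscosity":
            flu = FluidProperties(viscosity=value, density=fluid.density,
                                  surface_tension=fluid.surface_tension)
        elif parameter == "gelatin":
            sub = SubstrateProperties.from_gelatin(value, constants)
        dist = predict_ensemble(sample, cell, flu, sub, params, constants,
                                **ensemble_kwargs)
        rows.append({parameter: value, "mean_eta": dist.mean_eta,
                     "excluded_fraction": dist.excluded_fraction,
                     "n_droplets": len(sample)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Droplet tables: CSV with commented metadata header.
# Columns: diameter_um, velocity_m_s[, weight].  Hand-parsed so malformed
# rows can be reported with their line number.
# --------------------------------------------------------------------------

_META_KEYS = {"pressure": float, "distance": float, "viscosity": float, "label": str}


def write_droplet_table(sample: SpraySample, path: str | os.PathLike) -> None:
    """Write a spray sample as CSV (diameters in um) with ``# key: value``
    metadata header lines."""
    with open(path, "w", newline="") as fh:
        for key, value in sample.metadata.items():
            fh.write(f"# {key}: {value}\n")
        writer = csv.writer(fh)
        writer.writerow(["diameter_um", "velocity_m_s", "weight"])
        for o in sample.observations:
            writer.writerow([repr(o.d0 * 1e6), repr(o.v0), repr(o.weight)])


def read_droplet_table(path: str | os.PathLike) -> SpraySample:
    """Read a droplet table written by :func:`write_droplet_table` (or any
    CSV with ``diameter_um`` and ``velocity_m_s`` columns and an optional
    ``weight`` column).  Parse failures name the offending line."""
    metadata: dict = {}
    header: list[str] | None = None
    obs: list[DropletObservation] = []
    with open(path, "r", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key, value = key.strip(), value.strip()
                    caster = _META_KEYS.get(key, str)
                    try:
                        metadata[key] = caster(value)
                    except ValueError:
                        metadata[key] = value
                continue
            fields = next(csv.reader(io.StringIO(line)))
            if header is None:
                header = [f.strip() for f in fields]
                for col in ("diameter_um", "velocity_m_s"):
                    if col not in header:
                        raise ValueError(
                            f"{path}: line {lineno}: missing required column {col!r}")
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected at least two fields")
            row = dict(zip(header, (f.strip() for f in fields)))
            try:
                d_um = float(row["diameter_um"])
                v = float(row["velocity_m_s"])
                w = float(row.get("weight", "") or 1.0)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric or missing cell "
                                 f"({exc})") from None
            try:
                obs.append(DropletObservation(d_um * 1e-6, v, w))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if header is None:
        raise ValueError(f"{path}: empty file (no header row)")
    if not obs:
        raise ValueError(f"{path}: no droplet rows found")
    return SpraySample(tuple(obs), metadata)
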