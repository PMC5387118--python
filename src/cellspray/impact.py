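"""Single-cell survival after droplet impact.

The cell is treated as a small liquid droplet (diameter ``D_c``, viscosity
``mu_c``, density ``rho_c``, surface tension ``sigma_c``) carried inside a
larger bio-ink droplet that hits a substrate.  Impact flattens the cell into
an oblate spheroid; if the membrane area grows beyond a critical relative
expansion the membrane ruptures and the cell dies.  The chain implemented
here is:

1. map the (droplet, substrate) pair onto an equivalent hard-substrate
   impact (soft substrates cushion: larger effective diameter, lower
   effective velocity),
2. compute Weber/Reynolds numbers and the maximal spreading diameter of the
   bare cell and of the carrier droplet from a capillary-regime spreading
   law,
3. convert the bare-cell spreading into a Taylor-type deformation parameter,
   attenuate it by the cushioning of the surrounding droplet (bigger and
   less viscous droplets protect the cell), and convert back to a spreading
   diameter, clamped so the cell never spreads beyond its droplet,
4. evaluate the oblate-spheroid surface area, the relative membrane area
   ``gamma``, and the survival probability ``eta(gamma)``.

All quantities are SI internally.  Scalar entry points raise ``ValueError``
on domain violations; the vectorised helpers used by the ensemble machinery
assume validated input.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

logger = logging.getLogger("cellspray")

__all__ = [
    "CellProperties",
    "FluidProperties",
    "SubstrateProperties",
    "SurvivalParameters",
    "ModelConstants",
    "ImpactOutcome",
    "weber_number",
    "reynolds_number",
    "substrate_stiffness",
    "effective_impact",
    "bare_spreading_ratio",
    "spheroid_height",
    "deformation",
    "cushioned_deformation",
    "spreading_from_deformation",
    "clamp_spreading",
    "oblate_area",
    "survival_probability",
    "predict_single",
    "predict_eta",
    "validity_counts",
    "reset_validity_counts",
]

# --------------------------------------------------------------------------
# Validity bookkeeping: out-of-regime model evaluations warn once per
# category (single line) and are counted, never fatal.
# --------------------------------------------------------------------------

_validity_counter: Counter[str] = Counter()


def _count_validity(key: str, n: int, message: str) -> None:
    if n <= 0:
        return
    if _validity_counter[key] == 0:
        logger.warning("%s (further occurrences counted, not logged)", message)
    _validity_counter[key] += int(n)


def validity_counts() -> dict[str, int]:
    """Counts of out-of-validity model evaluations since the last reset."""
    return dict(_validity_counter)


def reset_validity_counts() -> None:
    _validity_counter.clear()


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class CellProperties:
    """The impacting cell modelled as a spherical liquid droplet.

    Defaults: a trypsinized mammalian cell — 13 um diameter, 12 mPa s
    effective viscosity, 1015 kg/m^3 density, 0.072 N/m surface tension.
    """

    diameter: float = 13e-6
    viscosity: float = 12e-3
    density: float = 1015.0
    surface_tension: float = 0.072

    def __post_init__(self) -> None:
        _require(self.diameter > 0, "cell diameter must be positive")
        _require(1e-6 <= self.diameter <= 1e-4,
                 "cell diameter outside the sane 1-100 um range")
        _require(self.viscosity > 0, "cell viscosity must be positive")
        _require(self.density > 0, "cell density must be positive")
        _require(self.surface_tension > 0, "cell surface tension must be positive")


@dataclass(frozen=True)
class FluidProperties:
    """Bio-ink (carrier droplet) liquid; defaults are water-like culture medium."""

    viscosity: float = 1e-3
    density: float = 1000.0
    surface_tension: float = 0.072

    def __post_init__(self) -> None:
        _require(self.viscosity > 0, "fluid viscosity must be positive")
        _require(self.density > 0, "fluid density must be positive")
        _require(self.surface_tension > 0, "fluid surface tension must be positive")


@dataclass(frozen=True)
class ModelConstants:
    """Fit constants of the impact model.

    cushioning_constant : C0 in the cushioning law (default 5).
    stiffness_constant  : C1 in S = min(1, C1 * gelatin_fraction) (default 5).
    weber_low           : Weber number below which cell deformation is a
                          small velocity-independent constant (default 5).
    literal_clamp       : if True, the final cell spreading is
                          min(bare-cell spreading, droplet spreading),
                          discarding the cushioned value; if False (default)
                          the cushioned spreading participates in the min.
    """

    cushioning_constant: float = 5.0
    stiffness_constant: float = 5.0
    weber_low: float = 5.0
    literal_clamp: bool = False

    def __post_init__(self) -> None:
        _require(self.cushioning_constant >= 0, "cushioning constant must be >= 0")
        _require(self.stiffness_constant > 0, "stiffness constant must be positive")
        _require(self.weber_low >= 0, "low-Weber threshold must be >= 0")


@dataclass(frozen=True)
class SubstrateProperties:
    """Substrate hardness: S = 0 liquid pool, S = 1 rigid surface.

    When built from a gelatin mass fraction, S = min(1, C1 * C_g).
    """

    stiffness: float = 1.0
    gelatin_fraction: float | None = None

    def __post_init__(self) -> None:
        _require(0.0 <= self.stiffness <= 1.0, "stiffness S must lie in [0, 1]")
        if self.gelatin_fraction is not None:
            _require(0.0 <= self.gelatin_fraction <= 1.0,
                     "gelatin mass fraction must lie in [0, 1]")

    @classmethod
    def from_gelatin(cls, gelatin_fraction: float,
                     constants: ModelConstants = ModelConstants()) -> "SubstrateProperties":
        s = substrate_stiffness(gelatin_fraction, constants)
        return cls(stiffness=s, gelatin_fraction=gelatin_fraction)

    @classmethod
    def hard(cls) -> "SubstrateProperties":
        return cls(stiffness=1.0)

    @classmethod
    def liquid_pool(cls) -> "SubstrateProperties":
        return cls(stiffness=0.0, gelatin_fraction=0.0)


@dataclass(frozen=True)
class SurvivalParameters:
    """Membrane-stretch survival law parameters.

    gamma_critical : relative membrane area at 50% survival (default 1.5).
    delta_gamma    : half-width of the partial-survival band (default 0.5,
                     i.e. full survival below gamma = 1.0 and certain death
                     above gamma = 2.0).
    """

    gamma_critical: float = 1.5
    delta_gamma: float = 0.5

    def __post_init__(self) -> None:
        _require(self.gamma_critical > 1.0, "critical expansion must exceed 1")
        _require(self.delta_gamma > 0.0, "partial-survival half-width must be positive")


@dataclass(frozen=True)
class ImpactOutcome:
    """Every intermediate of the impact chain for one droplet."""

    we_cell: float
    re_cell: float
    we_droplet: float
    re_droplet: float
    d_eff: float
    v_eff: float
    d_max_droplet: float
    d_max_cell_bare: float
    m_bare: float
    m_cushioned: float
    d_max_cell: float
    spheroid_height: float
    area_max: float
    gamma: float
    eta: float
    inputs: dict[str, Any] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in (
            "we_cell", "re_cell", "we_droplet", "re_droplet", "d_eff", "v_eff",
            "d_max_droplet", "d_max_cell_bare", "m_bare", "m_cushioned",
            "d_max_cell", "spheroid_height", "area_max", "gamma", "eta")}
        return d


# --------------------------------------------------------------------------
# Elementary operations (scalar-validated, numpy-compatible arithmetic)
# --------------------------------------------------------------------------


def weber_number(rho, velocity, diameter, sigma):
    """We = rho V^2 D / sigma: kinetic over surface energy of an impacting drop."""
    _require(bool(np.all(np.asarray(rho) > 0)) and bool(np.all(np.asarray(diameter) > 0))
             and bool(np.all(np.asarray(sigma) > 0)),
             "density, diameter and surface tension must be positive")
    _require(bool(np.all(np.asarray(velocity) >= 0)), "velocity must be non-negative")
    we = np.asarray(rho) * np.asarray(velocity) ** 2 * np.asarray(diameter) / np.asarray(sigma)
    return float(we) if np.ndim(we) == 0 else we


def reynolds_number(rho, velocity, diameter, mu):
    """Re = rho V D / mu: inertia over viscosity."""
    _require(bool(np.all(np.asarray(rho) > 0)) and bool(np.all(np.asarray(diameter) > 0))
             and bool(np.all(np.asarray(mu) > 0)),
             "density, diameter and viscosity must be positive")
    _require(bool(np.all(np.asarray(velocity) >= 0)), "velocity must be non-negative")
    re = np.asarray(rho) * np.asarray(velocity) * np.asarray(diameter) / np.asarray(mu)
    return float(re) if np.ndim(re) == 0 else re


def substrate_stiffness(gelatin_fraction: float,
                        constants: ModelConstants = ModelConstants()) -> float:
    """S = min(1, C1 * C_g); saturates at the hard-surface value for C_g >= 1/C1."""
    _require(0.0 <= gelatin_fraction <= 1.0, "gelatin mass fraction must lie in [0, 1]")
    return min(1.0, constants.stiffness_constant * gelatin_fraction)


def effective_impact(d0, v0, stiffness):
    """Equivalent hard-substrate impact for a droplet hitting a substrate of
    stiffness S.

    A drop impacting a deep liquid pool (S = 0) behaves, to first
    approximation, like a drop of diameter 2 D0 and velocity V0/2 on a hard
    wall; a rigid substrate (S = 1) leaves the impact unchanged.  In between
    the pair is interpolated linearly in S:

        D_eff = (2 - S) D0,     V_eff = (1 + S) V0 / 2.
    """
    s = np.asarray(stiffness, dtype=float)
    if np.any(s < 0.0) or np.any(s > 1.0):
        raise ValueError("stiffness S must lie in [0, 1]")
    d_eff = (2.0 - s) * np.asarray(d0, dtype=float)
    v_eff = 0.5 * (1.0 + s) * np.asarray(v0, dtype=float)
    if np.isscalar(d0) and np.isscalar(v0) and np.ndim(stiffness) == 0:
        return float(d_eff), float(v_eff)
    return d_eff, v_eff


def bare_spreading_ratio(we, re, constants: ModelConstants = ModelConstants()):
    """Maximal spreading ratio D_max/D of a Newtonian drop on a hard wall.

    Capillary-regime law D_max/D = We^(1/4) above the low-Weber threshold;
    below it the deformation is a small constant, the threshold value
    We_low^(1/4), so the two branches join continuously.  The branches are
    combined with a max so the ratio never dips below the low-We plateau.

    The capillary regime formally requires We <= Re^(4/5); violations are
    counted and warned once, never fatal (viscous cells routinely sit
    outside the strict regime).
    """
    we_arr = np.asarray(we, dtype=float)
    re_arr = np.asarray(re, dtype=float)
    if np.any(we_arr < 0):
        raise ValueError("Weber number must be non-negative")
    if np.any(re_arr < 0):
        raise ValueError("Reynolds number must be non-negative")
    low = constants.weber_low ** 0.25
    ratio = np.maximum(low, we_arr ** 0.25)
    above = we_arr > constants.weber_low
    n_bad = int(np.count_nonzero(above & (we_arr > re_arr ** 0.8)))
    _count_validity(
        "spreading_regime", n_bad,
        "spreading law evaluated outside its capillary-regime validity (We > Re^(4/5))")
    if np.ndim(we) == 0 and np.ndim(re) == 0:
        return float(ratio)
    return ratio


def spheroid_height(diameter, d_max):
    """Height of the oblate spheroid at maximal extension.

    Volume conservation, (pi/6) D_max^2 h = (pi/6) D^3, gives h = D^3/D_max^2.
    """
    d = np.asarray(diameter, dtype=float)
    dm = np.asarray(d_max, dtype=float)
    if np.any(d <= 0) or np.any(dm <= 0):
        raise ValueError("diameters must be positive")
    h = d**3 / dm**2
    return float(h) if np.ndim(diameter) == 0 and np.ndim(d_max) == 0 else h


def deformation(diameter, d_max):
    """Taylor-type deformation of the flattened cell.

    M0 = (D_max - h)/(D_max + h) with h the volume-conserving spheroid
    height; in terms of the spreading ratio r = D_max/D this is
    (r^3 - 1)/(r^3 + 1).  M0 = 0 for a sphere and M0 -> 1 for a plane.
    """
    d = np.asarray(diameter, dtype=float)
    dm = np.asarray(d_max, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    if np.any(dm < d):
        raise ValueError("maximal spreading diameter cannot be below the resting diameter")
    r3 = (dm / d) ** 3
    m = (r3 - 1.0) / (r3 + 1.0)
    return float(m) if np.ndim(diameter) == 0 and np.ndim(d_max) == 0 else m


def cushioned_deformation(m_bare, d_ratio, mu_ratio,
                          constants: ModelConstants = ModelConstants()):
    """Cell deformation after cushioning by the surrounding droplet.

    The surrounding liquid absorbs part of the impact: the larger the
    droplet relative to the cell (D0/Dc) and the lower its viscosity
    relative to the cell (mu_0/mu_c), the more the droplet flows around the
    comparatively stiff cell instead of dragging it flat.  The attenuation

        M = M0 ** k,    k = 1 + C0 (1 - Dc/D0) / (1 + mu_0/mu_c)

    reduces the bare deformation (M0 <= 1 so k >= 1 lowers it), reproduces
    the bare-cell limit M = M0 at D0 = Dc, decreases with droplet size and
    increases with droplet viscosity, and still saturates at M -> 1 for
    violent impacts so lethal deformations remain reachable however large
    the droplet.
    """
    m0 = np.asarray(m_bare, dtype=float)
    dr = np.asarray(d_ratio, dtype=float)
    mr = np.asarray(mu_ratio, dtype=float)
    if np.any(m0 < 0) or np.any(m0 > 1):
        raise ValueError("bare deformation must lie in [0, 1]")
    if np.any(dr < 1):
        raise ValueError("the droplet cannot be smaller than the cell (D0/Dc >= 1)")
    if np.any(mr <= 0):
        raise ValueError("viscosity ratio must be positive")
    k = 1.0 + constants.cushioning_constant * (1.0 - 1.0 / dr) / (1.0 + mr)
    m = m0 ** k
    if np.ndim(m_bare) == 0 and np.ndim(d_ratio) == 0 and np.ndim(mu_ratio) == 0:
        return float(m)
    return m


def spreading_from_deformation(m, diameter):
    """Invert the deformation: the spreading diameter whose Taylor
    deformation equals ``m``: D = Dc ((1+M)/(1-M))^(1/3)."""
    m_arr = np.asarray(m, dtype=float)
    d = np.asarray(diameter, dtype=float)
    if np.any(m_arr < 0) or np.any(m_arr >= 1):
        raise ValueError("deformation must lie in [0, 1); M = 1 means infinite spreading")
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = d * ((1.0 + m_arr) / (1.0 - m_arr)) ** (1.0 / 3.0)
    return float(out) if np.ndim(m) == 0 and np.ndim(diameter) == 0 else out


def clamp_spreading(d_from_m, d_cell_bare, d_droplet,
                    constants: ModelConstants = ModelConstants()):
    """Final cell spreading diameter.

    Default: min(cushioned spreading, bare-cell spreading, droplet
    spreading) — cushioning can only reduce spreading, and the flattened
    cell can never be wider than the spreading droplet that contains it.
    With ``literal_clamp`` the cushioned value is ignored and the result is
    min(bare-cell spreading, droplet spreading).
    """
    a = np.asarray(d_from_m, dtype=float)
    b = np.asarray(d_cell_bare, dtype=float)
    c = np.asarray(d_droplet, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0) or np.any(c <= 0):
        raise ValueError("spreading diameters must be positive")
    out = np.minimum(b, c) if constants.literal_clamp else np.minimum(a, np.minimum(b, c))
    scalar = all(np.ndim(x) == 0 for x in (d_from_m, d_cell_bare, d_droplet))
    return float(out) if scalar else out


def oblate_area(d_equatorial, height):
    """Surface area of an oblate spheroid with equatorial diameter D and
    polar diameter h <= D.

    A = 2 pi a^2 [1 + ((1-e^2)/e) artanh(e)], a = D/2, e^2 = 1 - (h/D)^2;
    reduces to the sphere area pi D^2 at h = D.
    """
    deq = np.asarray(d_equatorial, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(h <= 0):
        raise ValueError("height must be positive")
    if np.any(h > deq * (1 + 1e-12)):
        raise ValueError("prolate spheroids (h > D) are not modelled")
    ratio = np.minimum(h / deq, 1.0)
    e2 = 1.0 - ratio**2
    e = np.sqrt(np.maximum(e2, 0.0))
    a = deq / 2.0
    # artanh(e)/e -> 1 as e -> 0; series keeps the sphere limit smooth.
    small = e < 1e-7
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(small, 1.0 + e2 / 3.0, np.arctanh(np.where(small, 0.0, e)) / np.where(small, 1.0, e))
    area = 2.0 * np.pi * a**2 * (1.0 + (1.0 - e2) * factor)
    scalar = np.ndim(d_equatorial) == 0 and np.ndim(height) == 0
    return float(area) if scalar else area


def survival_probability(gamma, params: SurvivalParameters = SurvivalParameters()):
    """Survival probability as a function of relative membrane area.

    Piecewise-linear ramp: eta = 1 below gamma_critical - delta_gamma,
    eta = 0 above gamma_critical + delta_gamma, linear (and equal to 1/2 at
    gamma_critical) in between.  Compression (gamma < 1) does not damage the
    membrane, so gamma is floored at 1.
    """
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0):
        raise ValueError("relative membrane area must be non-negative")
    g = np.maximum(g, 1.0)
    eta = np.clip(
        (params.gamma_critical + params.delta_gamma - g) / (2.0 * params.delta_gamma),
        0.0, 1.0)
    return float(eta) if np.ndim(gamma) == 0 else eta


# --------------------------------------------------------------------------
# Full chain
# --------------------------------------------------------------------------


def _chain(d0, v0, cell: CellProperties, fluid: FluidProperties,
           substrate: SubstrateProperties, params: SurvivalParameters,
           constants: ModelConstants) -> dict[str, Any]:
    """Vectorised impact chain; assumes d0 >= cell diameter elementwise."""
    d_eff, v_eff = effective_impact(d0, v0, substrate.stiffness)
    d_eff = np.asarray(d_eff, dtype=float)
    v_eff = np.asarray(v_eff, dtype=float)

    we_c = cell.density * v_eff**2 * cell.diameter / cell.surface_tension
    re_c = cell.density * v_eff * cell.diameter / cell.viscosity
    we_0 = fluid.density * v_eff**2 * d_eff / fluid.surface_tension
    re_0 = fluid.density * v_eff * d_eff / fluid.viscosity

    ratio_c = bare_spreading_ratio(we_c, re_c, constants)
    ratio_0 = bare_spreading_ratio(we_0, re_0, constants)
    d_max_cell_bare = np.asarray(ratio_c) * cell.diameter
    d_max_droplet = np.asarray(ratio_0) * d_eff

    m_bare = deformation(cell.diameter, d_max_cell_bare)
    m = cushioned_deformation(m_bare, d_eff / cell.diameter,
                              fluid.viscosity / cell.viscosity, constants)
    d_from_m = spreading_from_deformation(m, cell.diameter)
    d_cell = clamp_spreading(d_from_m, d_max_cell_bare, d_max_droplet, constants)
    d_cell = np.maximum(d_cell, cell.diameter)  # clamp never compresses below rest
    h = spheroid_height(cell.diameter, d_cell)
    area = oblate_area(d_cell, h)
    gamma = np.maximum(np.asarray(area) / (np.pi * cell.diameter**2), 1.0)
    eta = survival_probability(gamma, params)

    return {
        "we_cell": we_c, "re_cell": re_c, "we_droplet": we_0, "re_droplet": re_0,
        "d_eff": d_eff, "v_eff": v_eff, "d_max_droplet": d_max_droplet,
        "d_max_cell_bare": d_max_cell_bare, "m_bare": m_bare, "m_cushioned": m,
        "d_max_cell": d_cell, "spheroid_height": h, "area_max": area,
        "gamma": gamma, "eta": eta,
    }


def predict_single(cell: CellProperties, d0: float, v0: float,
                   fluid: FluidProperties = FluidProperties(),
                   substrate: SubstrateProperties = SubstrateProperties.hard(),
                   params: SurvivalParameters = SurvivalParameters(),
                   constants: ModelConstants = ModelConstants()) -> ImpactOutcome:
    """Survival probability and all intermediates for one cell-containing
    droplet of diameter ``d0`` hitting at velocity ``v0``."""
    _require(d0 > 0, "droplet diameter must be positive")
    _require(v0 >= 0, "impact velocity must be non-negative")
    _require(d0 >= cell.diameter,
             f"droplet diameter {d0:g} m is below the cell diameter "
             f"{cell.diameter:g} m; the droplet cannot contain the cell")
    vals = _chain(d0, v0, cell, fluid, substrate, params, constants)
    scal = {k: float(np.asarray(v)) for k, v in vals.items()}
    return ImpactOutcome(
        **scal,
        inputs={"d0": d0, "v0": v0, "stiffness": substrate.stiffness,
                "cell": cell, "fluid": fluid},
    )


def predict_eta(d0, v0, cell: CellProperties = CellProperties(),
                fluid: FluidProperties = FluidProperties(),
                substrate: SubstrateProperties = SubstrateProperties.hard(),
                params: SurvivalParameters = SurvivalParameters(),
                constants: ModelConstants = ModelConstants()) -> np.ndarray:
    """Vectorised survival probabilities for arrays of droplet diameters and
    velocities (broadcast together).  Diameters must satisfy d0 >= Dc."""
    d0 = np.asarray(d0, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    if np.any(d0 < cell.diameter):
        raise ValueError("all droplet diameters must be >= the cell diameter; "
                         "filter or floor small droplets before calling")
    if np.any(v0 < 0):
        raise ValueError("velocities must be non-negative")
    return np.asarray(_chain(d0, v0, cell, fluid, substrate, params, constants)["eta"])
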