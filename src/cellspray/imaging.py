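"""Synthetic double-pulse shadowgraphy and droplet velocimetry.

Spray droplets are sized and tracked by backlit imaging: two light pulses
separated by a short delay expose two frames, droplets appear as dark disks
on a bright background, and the downward translation between frames gives
the impact velocity V0 = dh/dt.  Droplets far from the focal plane blur out
and are discarded by a sharpness gate, which confines the measurement to a
slab of roughly the focal-plane thickness around focus.

This module renders such image pairs from ground-truth droplets (dark disks,
depth-dependent Gaussian defocus blur, multiplicative shadow contrast,
seeded sensor noise) and implements the inverse pipeline: detection,
sharpness gating, sizing, frame-to-frame matching, and assembly of a
:class:`~cellspray.ensemble.SpraySample` ready for viability prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import measure

from .ensemble import DropletObservation, SpraySample
from .synth import SprayGeneratorConfig

__all__ = [
    "ImagingSetup",
    "GroundTruthDroplet",
    "Detection",
    "MatchResult",
    "CharacterizationResult",
    "render_pair",
    "detect",
    "match_and_measure",
    "characterize_spray",
    "write_image",
    "read_image",
]


@dataclass(frozen=True)
class ImagingSetup:
    """Geometry and radiometry of the shadowgraph.

    Defaults: 0.67 x 0.89 mm field of view at 1 um/pixel (670 x 890
    pixels), 1 us pulse separation, 0.1 mm focal-plane thickness.
    ``blur_coefficient`` sets the defocus model: the blur sigma of a droplet
    of pixel radius r at depth offset z is ``blur_coefficient * |z|/focal_thickness * r``.
    """

    fov_width: float = 0.67e-3
    fov_height: float = 0.89e-3
    pixel_size: float = 1e-6
    pulse_separation: float = 1e-6
    focal_thickness: float = 1e-4
    background: float = 0.85
    contrast: float = 0.9
    noise: float = 0.02
    blur_coefficient: float = 0.8

    def __post_init__(self) -> None:
        for name in ("fov_width", "fov_height", "pixel_size", "pulse_separation",
                     "focal_thickness", "background", "contrast"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the raster; rows run along the fall direction."""
        return (int(round(self.fov_height / self.pixel_size)),
                int(round(self.fov_width / self.pixel_size)))


@dataclass(frozen=True)
class GroundTruthDroplet:
    """A droplet to render: in-plane position (m, x across / y down from the
    top-left corner), depth offset from the focal plane (m), diameter (m),
    and velocity components (m/s, vy positive downward)."""

    x: float
    y: float
    depth: float
    diameter: float
    vx: float = 0.0
    vy: float = 0.0

    def __post_init__(self) -> None:
        if not 0.5e-6 <= self.diameter <= 120e-6:
            raise ValueError("ground-truth diameter outside the rendered 0.5-120 um range")

    @property
    def speed(self) -> float:
        return math.hypot(self.vx, self.vy)


@dataclass(frozen=True)
class Detection:
    """One gated detection: sub-pixel centre (row, col), diameter (m),
    sharpness score, frame index."""

    row: float
    col: float
    diameter: float
    sharpness: float
    frame: int = 0


@dataclass(frozen=True)
class MatchResult:
    observations: tuple[DropletObservation, ...]
    n_unmatched: int


@dataclass(frozen=True)
class CharacterizationResult:
    """Recovered spray sample plus the ground truth it was rendered from."""

    sample: SpraySample
    ground_truth: SpraySample
    n_pairs: int
    n_unmatched: int


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def _stamp_droplet(transmission: np.ndarray, row: float, col: float,
                   radius_px: float, sigma: float, contrast: float) -> None:
    """Multiply a (possibly defocused) dark disk into a transmission map."""
    half = int(math.ceil(radius_px + 4.0 * sigma + 3.0))
    r0, c0 = int(math.floor(row)), int(math.floor(col))
    rows, cols = transmission.shape
    rlo, rhi = r0 - half, r0 + half + 1
    clo, chi = c0 - half, c0 + half + 1
    if rhi <= 0 or rlo >= rows or chi <= 0 or clo >= cols:
        return  # fully outside the field of view: silently clipped
    rr = np.arange(max(rlo, 0), min(rhi, rows))
    cc = np.arange(max(clo, 0), min(chi, cols))
    if rr.size == 0 or cc.size == 0:
        return
    dist = np.hypot(rr[:, None] - row, cc[None, :] - col)
    alpha = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
    if sigma > 0.05:
        alpha = ndimage.gaussian_filter(alpha, sigma, mode="constant")
    transmission[rr[0]:rr[-1] + 1, cc[0]:cc[-1] + 1] *= 1.0 - contrast * alpha


def _render_frame(droplets: Sequence[GroundTruthDroplet], setup: ImagingSetup,
                  dt: float, rng: np.random.Generator) -> np.ndarray:
    shape = setup.shape
    transmission = np.ones(shape)
    px = setup.pixel_size
    for d in droplets:
        row = (d.y + d.vy * dt) / px
        col = (d.x + d.vx * dt) / px
        radius_px = d.diameter / (2.0 * px)
        sigma = setup.blur_coefficient * abs(d.depth) / setup.focal_thickness * radius_px
        _stamp_droplet(transmission, row, col, radius_px, sigma, setup.contrast)
    img = setup.background * transmission
    if setup.noise > 0:
        img = img + rng.normal(0.0, setup.noise, size=shape)
    return np.clip(img, 0.0, 1.0)


def render_pair(droplets: Sequence[GroundTruthDroplet],
                setup: ImagingSetup = ImagingSetup(),
                seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render the two exposures of a double-pulse shadowgraph.

    Frame 1 shows the droplets at their stated positions; frame 2 after one
    pulse separation of free flight.  Identical seeds give bit-identical
    images; droplets outside the field of view are silently clipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame1 = _render_frame(droplets, setup, 0.0, rng)
    frame2 = _render_frame(droplets, setup, setup.pulse_separation, rng)
    return frame1, frame2


# --------------------------------------------------------------------------
# Detection and sizing
# --------------------------------------------------------------------------

#: Default sharpness gate.  The score of a disk of pixel radius r is
#: roughly r/sigma_edge (edge steepness times radius over shadow depth), so
#: with the default blur model the gate passes droplets within about two
#: thirds of the focal-plane thickness and rejects everything beyond it.
DEFAULT_MIN_SHARPNESS = 0.7

_DETECT_LEVEL = 0.55       # candidate pixels: image < level * background
_MIN_REGION_AREA = 2       # px, speck rejection
_SMOOTH_SIGMA = 1.0        # px, denoising before masking and scoring
_MIN_FULLNESS = 0.75       # core shadow depth / full contrast; rejects |z| beyond ~0.75 focal thicknesses


def detect(image: np.ndarray, setup: ImagingSetup = ImagingSetup(),
           min_sharpness: float = DEFAULT_MIN_SHARPNESS,
           frame: int = 0) -> list[Detection]:
    """Detect sufficiently sharp dark disks in one shadowgraph frame.

    Candidate regions darker than the background are labelled; each is
    scored by edge sharpness (maximum intensity gradient times disk radius,
    normalized by the shadow depth) and sized by the area enclosed by the
    half-depth level.  Detections outside the 1-100 um range, touching the
    border, or below the sharpness gate are discarded.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / np.iinfo(image.dtype).max
    else:
        img = img.astype(float)

    # Light smoothing suppresses sensor noise before masking and scoring;
    # the half-level radius of a shadow edge is invariant under it.
    img_s = ndimage.gaussian_filter(img, _SMOOTH_SIGMA)
    bg = float(np.median(img_s))
    mask = img_s < _DETECT_LEVEL * bg
    labels, n = ndimage.label(mask)
    if n == 0:
        return []

    detections: list[Detection] = []
    rows, cols = img.shape
    for region in measure.regionprops(labels, intensity_image=img_s):
        if region.area < _MIN_REGION_AREA:
            continue
        rmin, cmin, rmax, cmax = region.bbox
        if rmin == 0 or cmin == 0 or rmax == rows or cmax == cols:
            continue  # touching the border: geometry unreliable
        pad = 3
        sl = (slice(max(rmin - pad, 0), min(rmax + pad, rows)),
              slice(max(cmin - pad, 0), min(cmax + pad, cols)))
        patch = img_s[sl]
        depth_img = np.maximum(bg - patch, 0.0)
        shadow_depth = float(depth_img.max())
        if shadow_depth <= 0:
            continue

        # Core saturation: an in-focus shadow absorbs the full contrast at
        # its centre, a defocused one does not; the ratio depends only on
        # blur-to-radius and so gates depth uniformly across droplet sizes.
        if shadow_depth / (setup.contrast * bg) < _MIN_FULLNESS:
            continue

        # sizing: area enclosed by the half-depth level, corrected for the
        # half-level erosion of a curved edge under the denoising blur
        half_mask = depth_img > 0.5 * shadow_depth
        area = int(half_mask.sum())
        radius_px = math.sqrt(max(area / math.pi + 0.5 * _SMOOTH_SIGMA**2, 0.0))
        diameter = 2.0 * radius_px * setup.pixel_size
        if not 1e-6 <= diameter <= 100e-6:
            continue

        gr, gc = np.gradient(patch)
        grad_max = float(np.hypot(gr, gc).max())
        sharpness = grad_max * radius_px / shadow_depth
        if sharpness < min_sharpness:
            continue

        w = depth_img * half_mask
        wsum = w.sum()
        rr = np.arange(sl[0].start, sl[0].stop)
        cc = np.arange(sl[1].start, sl[1].stop)
        crow = float((w.sum(axis=1) @ rr) / wsum)
        ccol = float((w.sum(axis=0) @ cc) / wsum)
        detections.append(Detection(crow, ccol, diameter, sharpness, frame))
    return detections


# --------------------------------------------------------------------------
# Matching and velocimetry
# --------------------------------------------------------------------------


def match_and_measure(frame1: Sequence[Detection], frame2: Sequence[Detection],
                      dt: float, setup: ImagingSetup = ImagingSetup(),
                      max_displacement: float = 60e-6,
                      max_diameter_mismatch: float = 0.25,
                      max_upward: float = 3e-6) -> MatchResult:
    """Pair detections across the two frames and convert displacement to
    velocity (V0 = dh/dt).

    One-to-one matching by globally optimal assignment on a cost combining
    displacement and relative diameter mismatch; pairs displaced more than
    ``max_displacement``, moving upward by more than ``max_upward``, or
    differing in diameter by more than ``max_diameter_mismatch`` (relative)
    are infeasible.  Unmatched detections are dropped and counted.
    """
    if dt <= 0:
        raise ValueError("pulse separation must be positive")
    if not frame1 or not frame2:
        return MatchResult((), len(frame1) + len(frame2))

    px = setup.pixel_size
    n1, n2 = len(frame1), len(frame2)
    cost = np.full((n1, n2), np.inf)
    for i, a in enumerate(frame1):
        for j, b in enumerate(frame2):
            disp = math.hypot(b.row - a.row, b.col - a.col) * px
            dmean = 0.5 * (a.diameter + b.diameter)
            mismatch = abs(a.diameter - b.diameter) / dmean
            upward = (a.row - b.row) * px  # rows increase downward
            if disp > max_displacement or mismatch > max_diameter_mismatch \
                    or upward > max_upward:
                continue
            cost[i, j] = disp / max_displacement + mismatch

    feasible = np.isfinite(cost)
    if not feasible.any():
        return MatchResult((), n1 + n2)
    big = 1e6
    rows, cols = linear_sum_assignment(np.where(feasible, cost, big))
    observations = []
    matched = 0
    for i, j in zip(rows, cols):
        if not feasible[i, j]:
            continue
        a, b = frame1[i], frame2[j]
        disp = math.hypot(b.row - a.row, b.col - a.col) * px
        observations.append(DropletObservation(
            d0=0.5 * (a.diameter + b.diameter), v0=disp / dt))
        matched += 1
    return MatchResult(tuple(observations), n1 + n2 - 2 * matched)


# --------------------------------------------------------------------------
# End-to-end characterization
# --------------------------------------------------------------------------


def characterize_spray(config: SprayGeneratorConfig,
                       setup: ImagingSetup = ImagingSetup(),
                       n_pairs: int = 400,
                       seed: int = 0,
                       droplets_per_pair: int = 8,
                       depth_range: float | None = None,
                       min_sharpness: float = DEFAULT_MIN_SHARPNESS) -> CharacterizationResult:
    """Simulate a full spray measurement: render ``n_pairs`` double-pulse
    image pairs of droplets drawn from the synthetic spray spectrum, detect
    and match them, and assemble the recovered :class:`SpraySample` together
    with the ground truth that was rendered.

    Depth offsets are uniform over ±``depth_range`` (default 1.5x the
    focal-plane thickness) so the sharpness gate is exercised; depth is
    independent of size and velocity, so gating does not bias the recovered
    means.
    """
    if n_pairs < 1:
        raise ValueError("need at least one image pair")
    if droplets_per_pair < 1:
        raise ValueError("need at least one droplet per pair")
    rng = np.random.default_rng(seed)
    if depth_range is None:
        depth_range = 1.5 * setup.focal_thickness

    from . import synth  # local import to keep module load cheap

    truth_d: list[float] = []
    truth_v: list[float] = []
    recovered: list[DropletObservation] = []
    n_unmatched = 0
    margin = 60e-6  # keep droplets off the border in both frames

    for _ in range(n_pairs):
        spectrum = synth.generate(config, droplets_per_pair, rng=rng)
        droplets = []
        for d0, v0 in zip(spectrum.diameters, spectrum.velocities):
            d0 = float(np.clip(d0, 1.5e-6, 95e-6))
            x = rng.uniform(margin, setup.fov_width - margin)
            y = rng.uniform(margin, setup.fov_height - margin)
            depth = rng.uniform(-depth_range, depth_range)
            vx = v0 * rng.normal(0.0, 0.03)
            droplets.append(GroundTruthDroplet(x, y, depth, d0, vx=vx, vy=float(v0)))
            truth_d.append(d0)
            truth_v.append(float(v0))
        img1, img2 = render_pair(droplets, setup, seed=rng)
        det1 = detect(img1, setup, min_sharpness=min_sharpness, frame=0)
        det2 = detect(img2, setup, min_sharpness=min_sharpness, frame=1)
        result = match_and_measure(det1, det2, setup.pulse_separation, setup)
        recovered.extend(result.observations)
        n_unmatched += result.n_unmatched

    if not recovered:
        raise ValueError("no droplets recovered; spray too sparse or gate too strict")
    meta = {"pressure": config.pressure, "distance": config.nozzle_distance,
            "viscosity": config.viscosity, "label": "shadowgraph characterization"}
    sample = SpraySample(tuple(recovered), meta)
    truth = SpraySample.from_arrays(truth_d, truth_v,
                                    metadata={**meta, "label": "ground truth"})
    return CharacterizationResult(sample, truth, n_pairs, n_unmatched)


# --------------------------------------------------------------------------
# Image IO (8/16-bit grayscale PNG or TIFF)
# --------------------------------------------------------------------------


def write_image(path: str, image: np.ndarray, bits: int = 8) -> None:
    """Write a float image in [0, 1] as 8- or 16-bit grayscale PNG/TIFF."""
    import imageio.v3 as iio

    if bits == 8:
        data = np.clip(np.round(image * 255), 0, 255).astype(np.uint8)
    elif bits == 16:
        data = np.clip(np.round(image * 65535), 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    iio.imwrite(path, data)


def read_image(path: str) -> np.ndarray:
    """Read a grayscale raster and normalize it to float in [0, 1]."""
    import imageio.v3 as iio

    data = iio.imread(path)
    if data.ndim == 3:
        data = data[..., 0]
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(float) / np.iinfo(data.dtype).max
    return data.astype(float)
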