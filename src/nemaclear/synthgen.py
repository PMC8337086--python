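"""Synthetic monolayer scenes with known ground truth.

Generates the four kinds of scenes the analysis pipeline consumes, each with
planted ground truth so every downstream stage is verifiable without real
microscopy data:

* ideal nematic director fields containing +-1/2 defects
  (``theta(x) = sum_i q_i * angle(x - x_i) + theta0``, mod pi, plus optional
  wrapped-Gaussian noise on the doubled angle);
* elongated-cell textures: white noise smoothed along the local director
  (line-integral-convolution style), emulating the high-aspect-ratio cell
  morphology;
* kinematic defect flow templates matching the observed sign structure --
  net inward flow along the comet axis at +1/2 defects, leg-convergent
  angular flow plus radially outward off-leg flow at -1/2 defects (these are
  templates, not hydrodynamic simulations);
* nuclear-stain images (inhomogeneous Poisson nuclei with Gaussian spots)
  and spheroid-clearance mask stacks (constant spheroid area, linearly
  growing cleared area).

All randomness flows from the single seed in :class:`SceneConfig`; fixed
seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .defects import DefectRecord, defect_axes
from .director import OrientationField, wrap_nematic
from .flow import VelocityField

__all__ = [
    "PlantedDefect",
    "SceneConfig",
    "ideal_director_field",
    "render_cell_texture",
    "defect_flow_field",
    "advect_image",
    "nuclei_image",
    "clearance_scene",
]

#: default pixel size so that a 16 px correlation spacing equals 10 um
DEFAULT_PIXEL_SIZE = 0.625


@dataclasses.dataclass
class PlantedDefect:
    """Ground-truth defect: position (x, y) um, charge +-1/2, phase theta0."""

    position: Tuple[float, float]
    charge: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.charge not in (0.5, -0.5):
            raise ValueError("charge must be +0.5 or -0.5")
        self.phase = float(wrap_nematic(self.phase))
        self.position = (float(self.position[0]), float(self.position[1]))


@dataclasses.dataclass
class SceneConfig:
    """Geometry, sampling, and noise settings shared by all generators.

    ``shape`` is the pixel grid ``(ny, nx)``; ``pixel_size`` is um/px;
    ``director_noise`` is the wrapped-Gaussian standard deviation (radians)
    added to the director angle; ``image_noise`` is additive Gaussian image
    noise in units of the texture's standard deviation; ``frame_interval`` is
    hours between frames (default 10 min, the velocity-imaging cadence).
    """

    shape: Tuple[int, int] = (512, 512)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    seed: int = 0
    director_noise: float = 0.0
    image_noise: float = 0.0
    frame_interval: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if min(self.shape) < 64:
            raise ValueError("grid must be at least 64x64")
        if self.director_noise < 0 or self.image_noise < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Deterministic generator; ``stream`` separates independent draws."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))

    @property
    def extent(self) -> Tuple[float, float]:
        """Physical size ``(x, y)`` in micrometres."""
        ny, nx = self.shape
        return (nx * self.pixel_size, ny * self.pixel_size)


def ideal_director_field(
    defects: Sequence[PlantedDefect],
    cfg: SceneConfig,
    stride: int = 1,
) -> OrientationField:
    """Analytic director field of superposed +-1/2 defects.

    ``theta(x) = sum_i q_i * atan2(y - y_i, x - x_i) + sum_i theta0_i``
    reduced mod pi (the standard additive nematic construction), plus
    wrapped-Gaussian noise of width ``cfg.director_noise`` on the angle.
    Coherence is the Gaussian attenuation ``exp(-2 sigma^2)`` of the nematic
    order parameter implied by that noise.  The planted defects are attached
    as ground truth in ``meta["planted"]``.

    Raises if any two defects are closer than 20 px (overlapping cores) or
    any position falls outside the grid.
    """
    defects = list(defects)
    xmax, ymax = cfg.extent
    for d in defects:
        if not (0 <= d.position[0] <= xmax and 0 <= d.position[1] <= ymax):
            raise ValueError(f"defect at {d.position} lies outside the grid")
    min_sep = 20 * cfg.pixel_size
    for i, a in enumerate(defects):
        for b in defects[i + 1:]:
            if np.hypot(a.position[0] - b.position[0], a.position[1] - b.position[1]) < min_sep:
                raise ValueError("overlapping defect cores (separation < 20 px)")
    gs = stride * cfg.pixel_size
    ny, nx = cfg.shape[0] // stride, cfg.shape[1] // stride
    x = np.arange(nx) * gs
    y = np.arange(ny) * gs
    xg, yg = np.meshgrid(x, y)
    theta = np.zeros((ny, nx))
    for d in defects:
        theta += d.charge * np.arctan2(yg - d.position[1], xg - d.position[0])
        theta += d.phase
    sigma = cfg.director_noise
    if sigma > 0:
        theta = theta + cfg.rng(stream=1).normal(0.0, sigma, size=theta.shape)
    coherence = np.full_like(theta, np.exp(-2.0 * sigma**2))
    return OrientationField(
        theta=wrap_nematic(theta),
        coherence=coherence,
        grid_spacing=gs,
        pixel_size=cfg.pixel_size,
        meta={"planted": defects},
    )


def render_cell_texture(
    field: OrientationField,
    streak_length: float,
    cfg: SceneConfig,
) -> np.ndarray:
    """Render an elongated-cell-like texture aligned with a director field.

    White noise is smoothed along the local director by averaging samples
    taken at ``+-k`` pixel steps along the director axis (line-integral
    convolution), then lightly blurred isotropically; the result has an
    autocorrelation elongated along the planted director, like the streaky
    texture of high-aspect-ratio cells.  ``streak_length`` is the full
    correlation length in micrometres (>= 2 px).

    Returns a float image of shape ``cfg.shape`` normalized to zero mean and
    unit variance, with additive noise ``cfg.image_noise``.
    """
    if streak_length < 2 * cfg.pixel_size:
        raise ValueError("streak_length must be at least 2 px equivalent")
    ny, nx = cfg.shape
    noise = cfg.rng(stream=2).standard_normal((ny, nx))
    # director sampled at every pixel
    px = cfg.pixel_size
    xg, yg = np.meshgrid(np.arange(nx) * px, np.arange(ny) * px)
    theta, _ = field.sample(xg, yg)
    ux, uy = np.cos(theta), np.sin(theta)
    # streak at the 2 px minimum means no directional pass: isotropic noise
    k_max = max(0, int(round(streak_length / (2 * cfg.pixel_size))) - 1)
    step = 1 if k_max <= 4 else 2  # sample every other pixel on long streaks
    acc = noise.copy()
    base_r = (yg / px).astype(np.float32)
    base_c = (xg / px).astype(np.float32)
    noise32 = noise.astype(np.float32)
    ux32, uy32 = ux.astype(np.float32), uy.astype(np.float32)
    for k in range(step, k_max + 1, step):
        for s in (+1.0, -1.0):
            coords = np.stack([base_r + np.float32(s * k) * uy32,
                               base_c + np.float32(s * k) * ux32])
            acc += ndimage.map_coordinates(noise32, coords, order=1, mode="wrap")
    img = ndimage.gaussian_filter(acc, 1.0, mode="wrap")
    img = (img - img.mean()) / img.std()
    if cfg.image_noise > 0:
        img = img + cfg.rng(stream=3).normal(0.0, cfg.image_noise, size=img.shape)
    return img


def defect_flow_field(
    defect: DefectRecord,
    v0: float,
    decay_length: float,
    cfg: SceneConfig,
    node_spacing: Optional[float] = None,
    leg_halfwidth: float = 45.0,
) -> VelocityField:
    """Kinematic velocity template around a single defect.

    +1/2 (in the defect frame with the comet tail along +x):
    ``vx = -v0 * sign(x) * exp(-r / decay_length), vy = 0`` -- net inward
    motion along the tail axis on both sides, as observed.  The template is
    rotated into the lab frame using the record's tail axis.

    -1/2: the angular component drives each point toward its nearest leg,
    ``v_phi = -v0 * exp(-r/L) * sin(3 * delta)`` where ``delta`` is the
    wrapped angular offset from the nearest leg; the radial component is
    ``+v0 * exp(-r/L)`` outside the leg bands (perpendicular distance >
    ``leg_halfwidth``) and zero on them -- convergence onto the legs with net
    outward flow elsewhere.

    The field is sampled on a node lattice spanning ``cfg.shape`` pixels with
    ``node_spacing`` micrometres between nodes (default 16 px, the
    correlation spacing).
    """
    if v0 < 0:
        raise ValueError("v0 must be non-negative")
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    if node_spacing is None:
        node_spacing = 16 * cfg.pixel_size
    xmax, ymax = cfg.extent
    nx = int(np.floor(xmax / node_spacing)) + 1
    ny = int(np.floor(ymax / node_spacing)) + 1
    x = np.arange(nx) * node_spacing
    y = np.arange(ny) * node_spacing
    xg, yg = np.meshgrid(x, y)
    dx = xg - defect.position[0]
    dy = yg - defect.position[1]
    r = np.hypot(dx, dy)
    envelope = v0 * np.exp(-r / decay_length)
    if defect.charge == 0.5:
        tail = defect.axes[0] if defect.axes else 0.0
        ca, sa = np.cos(tail), np.sin(tail)
        # coordinates in the defect frame (tail along +x)
        xf = ca * dx + sa * dy
        vxf = -np.sign(xf) * envelope
        vyf = np.zeros_like(vxf)
        vx = ca * vxf - sa * vyf
        vy = sa * vxf + ca * vyf
    elif defect.charge == -0.5:
        legs = np.asarray(defect.axes, dtype=float)
        if legs.shape != (3,):
            raise ValueError("-1/2 defect record must carry 3 leg axes")
        phi = np.arctan2(dy, dx)
        deltas = np.angle(np.exp(1j * (phi[..., None] - legs[None, None, :])))
        nearest = np.argmin(np.abs(deltas), axis=-1)
        delta = np.take_along_axis(deltas, nearest[..., None], axis=-1)[..., 0]
        v_phi = -envelope * np.sin(3 * delta)
        perp = r * np.abs(np.sin(delta))
        v_r = np.where(perp > leg_halfwidth, envelope, 0.0)
        cphi, sphi = np.cos(phi), np.sin(phi)
        vx = v_r * cphi - v_phi * sphi
        vy = v_r * sphi + v_phi * cphi
    else:
        raise ValueError(f"unknown defect charge {defect.charge}")
    core = r < node_spacing / 2
    vx = np.where(core, 0.0, vx)
    vy = np.where(core, 0.0, vy)
    return VelocityField(vx=vx, vy=vy, grid_spacing=node_spacing,
                         frame_interval=cfg.frame_interval)


def advect_image(
    image: np.ndarray,
    displacement,
    max_displacement: float = 32.0,
):
    """Warp an image by a per-pixel displacement (ground truth for PIV).

    ``displacement`` is either a constant ``(dx, dy)`` pair or a pair of
    per-pixel grids, in pixels; the warped image satisfies
    ``B(x) = A(x - d(x))`` (features move by +d) with bilinear interpolation.
    Displacements must stay below ``max_displacement`` (half a correlation
    subset).  Returns ``(warped, valid)`` where ``valid`` marks pixels whose
    source lay inside the image.
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    if np.isscalar(displacement[0]):
        dx = np.full((ny, nx), float(displacement[0]))
        dy = np.full((ny, nx), float(displacement[1]))
    else:
        dx = np.asarray(displacement[0], dtype=float)
        dy = np.asarray(displacement[1], dtype=float)
    if np.hypot(dx, dy).max() >= max_displacement:
        raise ValueError("displacement exceeds half the correlation subset")
    rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    src_r = rows - dy
    src_c = cols - dx
    warped = ndimage.map_coordinates(image, [src_r, src_c], order=1, mode="nearest")
    valid = (src_r >= 0) & (src_r <= ny - 1) & (src_c >= 0) & (src_c <= nx - 1)
    return warped, valid


def nuclei_image(
    density_fn: Callable,
    spot_sigma: float,
    intensity_per_cell: float,
    cfg: SceneConfig,
):
    """Nuclear-stain-like image: Poisson-placed Gaussian spots.

    ``density_fn`` maps positions (two arrays x, y in micrometres) to local
    density in cells/mm^2; nuclei are drawn from the corresponding
    inhomogeneous Poisson point process by thinning.  Each nucleus deposits a
    Gaussian spot of width ``spot_sigma`` (um) whose *integrated* intensity
    is ``intensity_per_cell`` (spots overlapping the border are clipped).

    Returns ``(image, positions)`` with positions of shape ``(n, 2)`` in um.
    """
    ny, nx = cfg.shape
    px = cfg.pixel_size
    xmax, ymax = cfg.extent
    # upper bound of the intensity over a coarse probe grid
    probe_x, probe_y = np.meshgrid(np.linspace(0, xmax, 64), np.linspace(0, ymax, 64))
    dens = np.asarray(density_fn(probe_x, probe_y), dtype=float)
    if np.any(dens < 0):
        raise ValueError("density_fn must be non-negative everywhere")
    lam_max = float(dens.max()) * 1.0001 / 1e6  # cells per um^2
    rng = cfg.rng(stream=4)
    image = np.zeros((ny, nx))
    if lam_max <= 0:
        return image, np.zeros((0, 2))
    n_prop = rng.poisson(lam_max * xmax * ymax)
    xs = rng.uniform(0, xmax, n_prop)
    ys = rng.uniform(0, ymax, n_prop)
    accept = rng.uniform(0, 1, n_prop) < np.asarray(density_fn(xs, ys), dtype=float) / (lam_max * 1e6)
    xs, ys = xs[accept], ys[accept]
    sig_px = spot_sigma / px
    half = max(2, int(np.ceil(4 * sig_px)))
    kern_axis = np.arange(-half, half + 1)
    for cx, cy in zip(xs / px, ys / px):
        ic, ir = int(round(cx)), int(round(cy))
        gx = np.exp(-((kern_axis + ic - cx) ** 2) / (2 * sig_px**2))
        gy = np.exp(-((kern_axis + ir - cy) ** 2) / (2 * sig_px**2))
        spot = np.outer(gy, gx)
        spot *= intensity_per_cell / (2 * np.pi * sig_px**2)
        r0, r1 = ir - half, ir + half + 1
        c0, c1 = ic - half, ic + half + 1
        rr0, rr1 = max(r0, 0), min(r1, ny)
        cc0, cc1 = max(c0, 0), min(c1, nx)
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        image[rr0:rr1, cc0:cc1] += spot[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0]
    if cfg.image_noise > 0:
        image = image + cfg.rng(stream=5).normal(0.0, cfg.image_noise, size=image.shape)
    positions = np.stack([xs, ys], axis=1) if len(xs) else np.zeros((0, 2))
    return image, positions


def clearance_scene(
    spheroid_area0: float,
    clear_rate: float,
    n_frames: int,
    cfg: SceneConfig,
    boundary_noise: float = 0.0,
    frame_interval: Optional[float] = None,
):
    """Two-channel mask stack emulating a spheroid clearance time-lapse.

    Channel 0 is the cancer-spheroid footprint (a disc of constant area
    ``spheroid_area0`` um^2); channel 1 is the cleared region of the
    mesothelial layer, a concentric disc whose area grows linearly,
    ``area(t) = clear_rate * t``.  ``boundary_noise`` perturbs each frame's
    cleared area multiplicatively (sigma as a fraction of the area),
    emulating segmentation jitter of a manually traced boundary.

    Returns ``(stack, table)``: a ``(n_frames, 2, ny, nx)`` uint8 mask stack
    and a DataFrame of the planted per-frame areas
    (``time_h, spheroid_area_um2, cleared_area_um2``).
    """
    if clear_rate < 0:
        raise ValueError("clear_rate must be non-negative")
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    if frame_interval is None:
        frame_interval = 1.0  # clearance assays are imaged hourly
    ny, nx = cfg.shape
    px = cfg.pixel_size
    cx, cy = nx * px / 2, ny * px / 2
    xg, yg = np.meshgrid(np.arange(nx) * px, np.arange(ny) * px)
    r2 = (xg - cx) ** 2 + (yg - cy) ** 2
    rng = cfg.rng(stream=6)
    times = np.arange(n_frames) * frame_interval
    r_sph = np.sqrt(spheroid_area0 / np.pi)
    stack = np.zeros((n_frames, 2, ny, nx), dtype=np.uint8)
    cleared = np.zeros(n_frames)
    for i, t in enumerate(times):
        area = clear_rate * t
        if boundary_noise > 0 and area > 0:
            area = max(0.0, area * (1.0 + rng.normal(0.0, boundary_noise)))
        cleared[i] = area
        stack[i, 0] = (r2 <= r_sph**2).astype(np.uint8)
        r_cl = np.sqrt(area / np.pi)
        stack[i, 1] = (r2 <= r_cl**2).astype(np.uint8)
    table = pd.DataFrame(
        {
            "time_h": times,
            "spheroid_area_um2": np.full(n_frames, float(spheroid_area0)),
            "cleared_area_um2": cleared,
        }
    )
    return stack, table


def planted_record(defect: PlantedDefect, field: OrientationField, frame: int = 0) -> DefectRecord:
    """Build a DefectRecord (with axes) from a planted ground-truth defect."""
    rec = DefectRecord(
        frame=frame,
        position=np.asarray(defect.position, dtype=float),
        charge=defect.charge,
        phase=defect.phase,
        core_coherence=1.0,
    )
    rec.axes = defect_axes(field, rec)
    return rec
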