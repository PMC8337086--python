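"""Velocity fields by subset correlation and defect-frame summaries.

Cell velocities are computed by digital image correlation of consecutive
frames: 64x64-pixel subsets spaced every 16 pixels (10 um at the default
pixel size) are matched by zero-normalized cross-correlation with a 3-point
Gaussian subpixel peak fit, and displacements are divided by the frame
interval.

For a +1/2 defect the field is rotated so the comet tail points along +x and
velocities are averaged in rectangular boxes to the left, right, top, and
bottom of the core (left/right boxes are 500 um wide by 750 um tall, with a
50 um separation between their inner edges).  For a -1/2 defect the angular
and radial components are averaged in six sectors delimited by the three
legs, excluding the central 250 um, a 45 um band along each leg, and radii
beyond 1800 um.
"""

from __future__ import annotations

import dataclasses
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "VelocityField",
    "PlusHalfSummary",
    "MinusHalfSummary",
    "piv_displacement",
    "rotate_frame",
    "plus_half_boxes",
    "polar_components",
    "minus_half_sectors",
    "control_summary",
]


@dataclasses.dataclass
class VelocityField:
    """Grid of 2-vector velocities in um/h on a regular node lattice.

    Node ``(iy, ix)`` sits at ``(x, y) = (ix, iy) * grid_spacing`` um in the
    y-up frame.  ``mask`` marks valid nodes; invalid nodes are excluded from
    every average.
    """

    vx: np.ndarray
    vy: np.ndarray
    grid_spacing: float
    frame_interval: float
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.vy.shape or self.vx.ndim != 2:
            raise ValueError("vx and vy must be 2-D grids of equal shape")
        if self.mask is None:
            self.mask = np.ones(self.vx.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.vx.shape:
            raise ValueError("mask shape mismatch")
        if self.grid_spacing <= 0 or self.frame_interval <= 0:
            raise ValueError("grid_spacing and frame_interval must be positive")

    @property
    def shape(self):
        return self.vx.shape

    def node_positions(self):
        ny, nx = self.vx.shape
        x = np.arange(nx) * self.grid_spacing
        y = np.arange(ny) * self.grid_spacing
        return np.meshgrid(x, y)

    @property
    def extent(self):
        ny, nx = self.vx.shape
        return ((nx - 1) * self.grid_spacing, (ny - 1) * self.grid_spacing)


class BoxMean(NamedTuple):
    mean_vx: float
    mean_vy: float
    n_nodes: int
    flagged: bool


@dataclasses.dataclass
class PlusHalfSummary:
    """Box-averaged velocities around a +1/2 defect (tail along +x)."""

    left: BoxMean
    right: BoxMean
    top: BoxMean
    bottom: BoxMean
    box_w: float
    box_h: float
    gap: float
    center: tuple


@dataclasses.dataclass
class MinusHalfSummary:
    """Sector-averaged velocities around a -1/2 defect."""

    mean_vphi_A: float
    mean_vphi_B: float
    mean_vr_on_leg: float
    mean_vr_off_leg: float
    n_A: int
    n_B: int
    n_on_leg: int
    n_off_leg: int
    r_min: float
    r_max: float
    leg_halfwidth: float
    leg_angles: tuple
    flags: tuple = ()


def _subset_grid(shape, subset_px: int, spacing_px: int):
    ny, nx = shape
    half = subset_px // 2
    rows = np.arange(half, ny - half + 1, spacing_px)
    cols = np.arange(half, nx - half + 1, spacing_px)
    return rows, cols


def piv_displacement(
    img_a,
    img_b,
    subset_px: int = 64,
    spacing_px: int = 16,
    pixel_size: float = 0.625,
    frame_interval: float = 1.0 / 6.0,
    peak_min: float = 0.3,
) -> VelocityField:
    """Velocity field from an image pair by zero-normalized correlation.

    Each subset of ``img_a`` is circularly cross-correlated against the
    co-located subset of ``img_b``; the correlation peak (wrapped to
    +-subset/2) gives the displacement, refined per axis with a 3-point
    Gaussian fit.  Subsets whose normalized peak falls below ``peak_min``,
    whose displacement reaches a quarter of the subset, or which are constant
    are masked invalid rather than raising.

    Velocity is ``displacement * pixel_size / frame_interval`` (um/h).
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must be 2-D and share a shape")
    if min(a.shape) < 2 * subset_px:
        raise ValueError("images must span at least two subsets per axis")
    rows, cols = _subset_grid(a.shape, subset_px, spacing_px)
    half = subset_px // 2
    n = subset_px
    limit = subset_px // 4
    # zero-pad just past the searched lag range: linear correlation there,
    # aliased contributions fall outside the +-limit window
    m = n + 2 * limit
    vx = np.zeros((len(rows), len(cols)))
    vy = np.zeros_like(vx)
    mask = np.zeros(vx.shape, dtype=bool)

    win_a = np.lib.stride_tricks.sliding_window_view(a, (n, n))
    win_b = np.lib.stride_tricks.sliding_window_view(b, (n, n))
    r_idx = rows - half
    c_idx = cols - half
    # per-lag overlap count removes the triangular bias toward zero lag
    lags = np.arange(-limit, limit + 1)
    overlap = (n - np.abs(lags))[:, None] * (n - np.abs(lags))[None, :]

    for i, r0 in enumerate(r_idx):
        sa = win_a[r0, c_idx].astype(np.float32)  # (ncols, n, n)
        sb = win_b[r0, c_idx].astype(np.float32)
        sa = sa - sa.mean(axis=(1, 2), keepdims=True)
        sb = sb - sb.mean(axis=(1, 2), keepdims=True)
        sig_a = np.sqrt((sa**2).mean(axis=(1, 2)))
        sig_b = np.sqrt((sb**2).mean(axis=(1, 2)))
        ok = (sig_a > 1e-12) & (sig_b > 1e-12)
        pa = np.zeros((len(c_idx), m, m), dtype=np.float32)
        pb = np.zeros_like(pa)
        pa[:, :n, :n] = sa
        pb[:, :n, :n] = sb
        corr = np.fft.irfft2(np.conj(np.fft.rfft2(pa)) * np.fft.rfft2(pb), s=(m, m))
        # restrict to lags within +-limit; lag s lives at index s mod m
        ix = np.ix_(lags % m, lags % m)
        corr = corr[:, ix[0], ix[1]].astype(float)
        denom = np.where(ok, sig_a * sig_b, 1.0).astype(float)
        coef = corr / overlap[None, :, :] / denom[:, None, None]
        flat = coef.reshape(len(c_idx), -1)
        peak_idx = np.argmax(flat, axis=1)
        peak_val = flat[np.arange(len(c_idx)), peak_idx]
        pr, pc = np.unravel_index(peak_idx, coef.shape[1:])
        for j in range(len(c_idx)):
            if not ok[j]:
                continue
            dy = int(lags[pr[j]])
            dx = int(lags[pc[j]])
            on_edge = pr[j] in (0, len(lags) - 1) or pc[j] in (0, len(lags) - 1)
            if on_edge or peak_val[j] < peak_min:
                continue
            patch = coef[j, pr[j] - 1:pr[j] + 2, pc[j] - 1:pc[j] + 2]
            sx, sy = _subpixel_2d(patch)
            vx[i, j] = (dx + sx) * pixel_size / frame_interval
            vy[i, j] = (dy + sy) * pixel_size / frame_interval
            mask[i, j] = True
    return VelocityField(
        vx=vx, vy=vy, mask=mask,
        grid_spacing=spacing_px * pixel_size,
        frame_interval=frame_interval,
    )


# quadratic design matrix on the 3x3 neighborhood (1, x, y, x^2, y^2, xy)
_OFFS = np.array([(dx, dy) for dy in (-1, 0, 1) for dx in (-1, 0, 1)], dtype=float)
_DESIGN = np.stack([
    np.ones(9), _OFFS[:, 0], _OFFS[:, 1],
    _OFFS[:, 0] ** 2, _OFFS[:, 1] ** 2, _OFFS[:, 0] * _OFFS[:, 1],
], axis=1)
_DESIGN_PINV = np.linalg.pinv(_DESIGN)


def _subpixel_2d(patch: np.ndarray) -> tuple:
    """Subpixel peak offset from a 3x3 neighborhood.

    Fits a full 2-D quadratic (with cross term, i.e. an elliptical Gaussian
    in log space when all values are positive) so that ridge-like peaks of
    anisotropic textures are located without axis bias.  Offsets are clipped
    to +-1 px.
    """
    vals = patch.reshape(9)
    use_log = np.all(vals > 0)
    z = np.log(vals) if use_log else vals
    _, q1, q2, q3, q4, q5 = _DESIGN_PINV @ z
    hxx, hyy, hxy = 2 * q3, 2 * q4, q5
    det = hxx * hyy - hxy**2
    # require a proper maximum (negative-definite Hessian)
    if det <= 0 or hxx >= 0:
        return 0.0, 0.0
    dx = (-q1 * hyy + q2 * hxy) / det
    dy = (-q2 * hxx + q1 * hxy) / det
    return float(np.clip(dx, -1.0, 1.0)), float(np.clip(dy, -1.0, 1.0))


def rotate_frame(field: VelocityField, center, tail_angle: float) -> VelocityField:
    """Rotate a velocity field by ``-tail_angle`` about ``center``.

    Positions AND vectors are rotated so that a feature originally at
    direction ``tail_angle`` from the center (e.g. a +1/2 comet tail) ends up
    along +x.  The result is resampled onto the original regular grid by
    bilinear interpolation; the validity mask is propagated conservatively.
    """
    cx, cy = float(center[0]), float(center[1])
    gs = field.grid_spacing
    xg, yg = field.node_positions()
    ca, sa = np.cos(tail_angle), np.sin(tail_angle)
    # source position: rotate output node by +tail_angle about the center
    dx, dy = xg - cx, yg - cy
    sx = cx + ca * dx - sa * dy
    sy = cy + sa * dx + ca * dy
    coords = np.stack([sy / gs, sx / gs])
    vxs = ndimage.map_coordinates(field.vx, coords, order=1, mode="constant", cval=0.0)
    vys = ndimage.map_coordinates(field.vy, coords, order=1, mode="constant", cval=0.0)
    ms = ndimage.map_coordinates(field.mask.astype(float), coords, order=1,
                                 mode="constant", cval=0.0)
    ny, nx = field.shape
    inside = (sx >= 0) & (sy >= 0) & (sx <= (nx - 1) * gs) & (sy <= (ny - 1) * gs)
    mask = (ms > 0.999) & inside
    # rotate the sampled vectors into the defect frame
    vx_new = ca * vxs + sa * vys
    vy_new = -sa * vxs + ca * vys
    return VelocityField(vx=vx_new, vy=vy_new, mask=mask,
                         grid_spacing=gs, frame_interval=field.frame_interval)


def _box_mean(field: VelocityField, x_lo, x_hi, y_lo, y_hi, min_nodes: int = 10) -> BoxMean:
    xg, yg = field.node_positions()
    sel = (xg >= x_lo) & (xg <= x_hi) & (yg >= y_lo) & (yg <= y_hi) & field.mask
    n = int(sel.sum())
    if n == 0:
        return BoxMean(float("nan"), float("nan"), 0, True)
    return BoxMean(float(field.vx[sel].mean()), float(field.vy[sel].mean()), n, n < min_nodes)


def plus_half_boxes(
    field: VelocityField,
    center,
    box_w: float = 500.0,
    box_h: float = 750.0,
    gap: float = 50.0,
) -> PlusHalfSummary:
    """Average velocities in boxes left/right/top/bottom of a +1/2 core.

    ``field`` must already be in the defect frame (tail along +x).  The
    left/right boxes are ``box_w`` wide by ``box_h`` tall with inner edges
    ``gap/2`` from the center (total separation ``gap``); the top/bottom
    boxes are transposed (``box_h`` wide by ``box_w`` tall).  Boxes with
    fewer than 10 valid nodes are flagged.
    """
    cx, cy = float(center[0]), float(center[1])
    g2 = gap / 2
    right = _box_mean(field, cx + g2, cx + g2 + box_w, cy - box_h / 2, cy + box_h / 2)
    left = _box_mean(field, cx - g2 - box_w, cx - g2, cy - box_h / 2, cy + box_h / 2)
    top = _box_mean(field, cx - box_h / 2, cx + box_h / 2, cy + g2, cy + g2 + box_w)
    bottom = _box_mean(field, cx - box_h / 2, cx + box_h / 2, cy - g2 - box_w, cy - g2)
    return PlusHalfSummary(left=left, right=right, top=top, bottom=bottom,
                           box_w=box_w, box_h=box_h, gap=gap, center=(cx, cy))


def polar_components(field: VelocityField, center):
    """Radial and angular velocity grids about ``center``.

    ``v_r = v . r_hat`` and ``v_phi = v . phi_hat`` with ``phi_hat``
    counterclockwise, so ``v_r**2 + v_phi**2 == |v|**2`` at every node.  The
    node at the center (r < half a grid spacing) is masked; a matching
    validity mask is returned.
    """
    cx, cy = float(center[0]), float(center[1])
    xg, yg = field.node_positions()
    dx, dy = xg - cx, yg - cy
    r = np.hypot(dx, dy)
    ok = r >= field.grid_spacing / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        cphi = np.where(ok, dx / np.maximum(r, 1e-300), 0.0)
        sphi = np.where(ok, dy / np.maximum(r, 1e-300), 0.0)
    v_r = field.vx * cphi + field.vy * sphi
    v_phi = -field.vx * sphi + field.vy * cphi
    return v_r, v_phi, field.mask & ok


def minus_half_sectors(
    field: VelocityField,
    center,
    leg_angles: Sequence[float],
    r_min: float = 250.0,
    leg_halfwidth: float = 45.0,
    r_max: float = 1800.0,
) -> MinusHalfSummary:
    """Sector averages of angular and radial velocity around a -1/2 defect.

    The annulus ``r_min <= r <= r_max`` is partitioned by the three legs into
    six sectors.  A point's nearest leg is found from its wrapped angular
    offset ``delta``; nodes within ``leg_halfwidth`` perpendicular distance
    of a leg ray form the on-leg band.  Off-leg nodes are labeled A when they
    sit on the clockwise side of their nearest leg (``delta < 0``; those
    cells converge counterclockwise onto the leg) and B on the
    counterclockwise side.  Sector groups with fewer than 10 valid nodes are
    flagged.
    """
    legs = np.asarray(leg_angles, dtype=float)
    if legs.shape != (3,):
        raise ValueError("exactly 3 leg angles are required")
    cx, cy = float(center[0]), float(center[1])
    v_r, v_phi, ok = polar_components(field, center)
    xg, yg = field.node_positions()
    dx, dy = xg - cx, yg - cy
    r = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    annulus = ok & (r >= r_min) & (r <= r_max)
    # wrapped offset to each leg, pick nearest
    deltas = np.angle(np.exp(1j * (phi[..., None] - legs[None, None, :])))
    nearest = np.argmin(np.abs(deltas), axis=-1)
    delta = np.take_along_axis(deltas, nearest[..., None], axis=-1)[..., 0]
    perp = r * np.abs(np.sin(delta))
    on_leg = annulus & (perp <= leg_halfwidth)
    off_leg = annulus & ~on_leg
    sel_a = off_leg & (delta < 0)
    sel_b = off_leg & (delta >= 0)

    def mean_of(v, sel):
        n = int(sel.sum())
        return (float(v[sel].mean()) if n else float("nan")), n

    m_a, n_a = mean_of(v_phi, sel_a)
    m_b, n_b = mean_of(v_phi, sel_b)
    m_on, n_on = mean_of(v_r, on_leg)
    m_off, n_off = mean_of(v_r, off_leg)
    flags = tuple(
        name for name, n in (("A", n_a), ("B", n_b), ("on_leg", n_on), ("off_leg", n_off))
        if n < 10
    )
    return MinusHalfSummary(
        mean_vphi_A=m_a, mean_vphi_B=m_b, mean_vr_on_leg=m_on, mean_vr_off_leg=m_off,
        n_A=n_a, n_B=n_b, n_on_leg=n_on, n_off_leg=n_off,
        r_min=r_min, r_max=r_max, leg_halfwidth=leg_halfwidth,
        leg_angles=tuple(float(a) for a in legs), flags=flags,
    )


def control_summary(
    field: VelocityField,
    n_boxes: int,
    box_w: float = 500.0,
    box_h: float = 750.0,
    gap: float = 50.0,
    seed: int = 0,
    defect_positions: Sequence = (),
    margin: float = 100.0,
    max_tries: int = 2000,
) -> List[PlusHalfSummary]:
    """Box summaries at seeded random defect-free control positions.

    The same box geometry as :func:`plus_half_boxes` is applied at random
    centers chosen so the boxes fit inside the field and no known defect lies
    within the box footprint plus ``margin`` micrometres.  Raises if no
    qualifying position can be found.
    """
    rng = np.random.default_rng(seed)
    xmax, ymax = field.extent
    half_x = gap / 2 + max(box_w, box_h / 2)
    half_y = max(box_h / 2, gap / 2 + box_w)
    if xmax < 2 * half_x or ymax < 2 * half_y:
        raise ValueError("field too small for the requested control boxes")
    clearance = float(np.hypot(half_x, half_y)) + margin
    out: List[PlusHalfSummary] = []
    tries = 0
    defect_positions = [np.asarray(p, dtype=float) for p in defect_positions]
    while len(out) < n_boxes:
        tries += 1
        if tries > max_tries:
            raise ValueError("no defect-free region large enough for control boxes")
        cx = rng.uniform(half_x, xmax - half_x)
        cy = rng.uniform(half_y, ymax - half_y)
        if any(np.hypot(cx - p[0], cy - p[1]) < clearance for p in defect_positions):
            continue
        out.append(plus_half_boxes(field, (cx, cy), box_w=box_w, box_h=box_h, gap=gap))
    return out
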