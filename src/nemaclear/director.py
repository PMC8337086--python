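"""Local cell-orientation (director) estimation from monolayer images.

Elongated cells in a confluent monolayer align with their neighbours.  The
local alignment is a *nematic* director: a headless orientation angle
``theta`` in ``[0, pi)`` (``theta`` and ``theta + pi`` are the same state).
The director and its degree of local order (coherence) are estimated from a
grayscale image with the classic structure-tensor method: image gradients are
computed at a fine scale ``gradient_sigma``, their outer products are averaged
over a window ``window_sigma`` (about one cell width), and the direction of
*least* intensity variation -- the minor eigenvector of the averaged tensor --
is the streak axis of the elongated cells.

Conventions
-----------
Arrays are indexed ``[iy, ix]`` in a mathematical, y-up frame: node ``(iy,
ix)`` sits at position ``(x, y) = (ix, iy) * grid_spacing`` in micrometres and
angles are measured counterclockwise from the +x axis.  Images read from disk
should be flipped row-wise first (see :mod:`nemaclear.io`) so that the
counterclockwise-positive sign convention used by the flow analysis is
unambiguous.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "OrientationField",
    "wrap_nematic",
    "nematic_difference",
    "structure_tensor",
    "director_field",
    "downsample_field",
    "estimate_director",
]


def wrap_nematic(theta):
    """Wrap angles into the nematic fundamental domain ``[0, pi)``.

    ``np.mod`` can round a negative angle infinitesimally below a multiple
    of pi up to pi itself; that boundary value is folded back to 0.
    """
    w = np.mod(theta, np.pi)
    return np.where(w >= np.pi, 0.0, w) if np.ndim(w) else (0.0 if w >= np.pi else float(w))


def nematic_difference(a, b):
    """Signed nematic difference ``a - b`` wrapped into ``(-pi/2, pi/2]``.

    This is the smallest rotation carrying director ``b`` onto director ``a``
    given the head-tail symmetry ``theta == theta + pi``.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return np.pi / 2 - np.mod(np.pi / 2 - d, np.pi)


@dataclasses.dataclass
class OrientationField:
    """Grid of director angles with per-node coherence.

    Parameters
    ----------
    theta:
        Angles in radians, wrapped to ``[0, pi)``, shape ``(ny, nx)``.
    coherence:
        Local nematic order in ``[0, 1]`` (0 isotropic, 1 perfectly aligned).
    grid_spacing:
        Distance between neighbouring nodes in micrometres.
    pixel_size:
        Micrometres per pixel of the source image.
    origin:
        Marker for the row orientation convention; ``"lower"`` means row
        index increases with y (mathematical frame).
    meta:
        Free-form metadata (e.g. planted ground truth for synthetic fields).
    """

    theta: np.ndarray
    coherence: np.ndarray
    grid_spacing: float
    pixel_size: float
    origin: str = "lower"
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.coherence = np.asarray(self.coherence, dtype=float)
        if self.theta.shape != self.coherence.shape:
            raise ValueError("theta and coherence must have the same shape")
        if self.theta.ndim != 2:
            raise ValueError("theta must be a 2-D grid")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta contains non-finite values")
        if np.any(self.coherence < -1e-12) or np.any(self.coherence > 1 + 1e-12):
            raise ValueError("coherence must lie in [0, 1]")
        if self.grid_spacing <= 0 or self.pixel_size <= 0:
            raise ValueError("grid_spacing and pixel_size must be positive")
        self.theta = wrap_nematic(self.theta)
        self.coherence = np.clip(self.coherence, 0.0, 1.0)

    @property
    def shape(self) -> tuple:
        return self.theta.shape

    def node_positions(self):
        """Return ``(x, y)`` coordinate grids of the nodes in micrometres."""
        ny, nx = self.theta.shape
        x = np.arange(nx) * self.grid_spacing
        y = np.arange(ny) * self.grid_spacing
        return np.meshgrid(x, y)

    @property
    def extent(self):
        """``(xmax, ymax)`` of the node lattice in micrometres."""
        ny, nx = self.theta.shape
        return ((nx - 1) * self.grid_spacing, (ny - 1) * self.grid_spacing)

    def nematic_tensor(self):
        """Coherence-weighted nematic tensor components ``(Qxx, Qxy)``.

        ``Qyy = -Qxx`` for the traceless 2-D tensor, so two components
        suffice: ``Qxx = c cos 2theta``, ``Qxy = c sin 2theta``.
        """
        qxx = self.coherence * np.cos(2 * self.theta)
        qxy = self.coherence * np.sin(2 * self.theta)
        return qxx, qxy

    def sample(self, x, y):
        """Interpolate ``(theta, coherence)`` at positions in micrometres.

        Interpolation is performed on the nematic tensor, never on raw
        angles, so it is continuous across the ``0 == pi`` wrap.
        """
        scalar = np.isscalar(x) or (np.ndim(x) == 0)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        coords = np.stack([y / self.grid_spacing, x / self.grid_spacing])
        qxx, qxy = self.nematic_tensor()
        n = ndimage.map_coordinates(qxx, coords, order=1, mode="nearest")
        m = ndimage.map_coordinates(qxy, coords, order=1, mode="nearest")
        w = ndimage.map_coordinates(self.coherence, coords, order=1, mode="nearest")
        theta = wrap_nematic(0.5 * np.arctan2(m, n))
        mag = np.hypot(n, m)
        coh = np.where(w > 1e-12, np.minimum(mag / np.maximum(w, 1e-12), 1.0), 0.0)
        if scalar:
            return float(theta[0]), float(coh[0])
        return theta, coh


def structure_tensor(image, gradient_sigma: float = 2.0, window_sigma: float = 16.0):
    """Gaussian-gradient structure tensor of a grayscale image.

    Returns the per-pixel components ``(Jxx, Jxy, Jyy)`` where
    ``Jab = <Ia * Ib>`` averaged with a Gaussian window.  The tensor is
    symmetric positive semi-definite by construction.

    Parameters
    ----------
    image:
        2-D grayscale array (y-up convention), finite values only.
    gradient_sigma:
        Scale (px) of the Gaussian-derivative gradient filters.
    window_sigma:
        Scale (px) of the averaging window; must be >= ``gradient_sigma``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if not (window_sigma >= gradient_sigma >= 1.0):
        raise ValueError("require window_sigma >= gradient_sigma >= 1 px")
    # axis 0 is y in the math frame, axis 1 is x
    gy = ndimage.gaussian_filter(image, gradient_sigma, order=(1, 0), mode="nearest")
    gx = ndimage.gaussian_filter(image, gradient_sigma, order=(0, 1), mode="nearest")
    jxx = ndimage.gaussian_filter(gx * gx, window_sigma, mode="nearest")
    jxy = ndimage.gaussian_filter(gx * gy, window_sigma, mode="nearest")
    jyy = ndimage.gaussian_filter(gy * gy, window_sigma, mode="nearest")
    return jxx, jxy, jyy


def director_field(jxx, jxy, jyy, pixel_size: float, stride: int = 16) -> OrientationField:
    """Extract the director and coherence from structure-tensor grids.

    The director is the *minor* eigenvector of J (direction of least
    intensity variation, i.e. the cell streak axis), mapped to ``[0, pi)``.
    Coherence is ``(l1 - l2) / (l1 + l2)`` with the convention 0 where the
    tensor vanishes.  The output grid subsamples the pixel grid by ``stride``.
    """
    jxx = np.asarray(jxx, dtype=float)
    jxy = np.asarray(jxy, dtype=float)
    jyy = np.asarray(jyy, dtype=float)
    if not (jxx.shape == jxy.shape == jyy.shape):
        raise ValueError("tensor grids must share a shape")
    if stride < 1 or int(stride) != stride:
        raise ValueError("stride must be a positive integer")
    stride = int(stride)
    jxx, jxy, jyy = (a[::stride, ::stride] for a in (jxx, jxy, jyy))
    # major eigenvector (gradient direction) angle, then rotate 90 deg
    major = 0.5 * np.arctan2(2 * jxy, jxx - jyy)
    theta = wrap_nematic(major + np.pi / 2)
    trace = jxx + jyy
    split = np.sqrt((jxx - jyy) ** 2 + 4 * jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(trace > 1e-300, split / np.maximum(trace, 1e-300), 0.0)
    return OrientationField(
        theta=theta,
        coherence=np.clip(coherence, 0.0, 1.0),
        grid_spacing=stride * pixel_size,
        pixel_size=pixel_size,
    )


def downsample_field(field: OrientationField, factor: int) -> OrientationField:
    """Coarsen an orientation field by block-averaging the nematic tensor.

    Averaging is done on coherence-weighted ``(cos 2theta, sin 2theta)``,
    never on raw angles, so antipodal directors (e.g. 10 deg and 170 deg)
    average to their nematic mean (0 deg), not the arithmetic one.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    ny, nx = field.shape
    if factor > min(ny, nx):
        raise ValueError("factor larger than grid")
    if factor == 1:
        return OrientationField(
            field.theta.copy(), field.coherence.copy(),
            field.grid_spacing, field.pixel_size, field.origin, dict(field.meta),
        )
    my, mx = (ny // factor) * factor, (nx // factor) * factor
    qxx, qxy = field.nematic_tensor()

    def block_mean(a):
        return a[:my, :mx].reshape(my // factor, factor, mx // factor, factor).mean(axis=(1, 3))

    n = block_mean(qxx)
    m = block_mean(qxy)
    w = block_mean(field.coherence)
    theta = wrap_nematic(0.5 * np.arctan2(m, n))
    mag = np.hypot(n, m)
    coherence = np.where(w > 1e-12, np.minimum(mag / np.maximum(w, 1e-12), 1.0), 0.0)
    return OrientationField(
        theta=theta,
        coherence=coherence,
        grid_spacing=field.grid_spacing * factor,
        pixel_size=field.pixel_size,
        origin=field.origin,
        meta=dict(field.meta),
    )


def estimate_director(
    image,
    pixel_size: float,
    gradient_sigma: float = 2.0,
    window_sigma: float = 16.0,
    stride: int = 16,
) -> OrientationField:
    """Convenience wrapper: structure tensor + director extraction."""
    jxx, jxy, jyy = structure_tensor(image, gradient_sigma, window_sigma)
    return director_field(jxx, jxy, jyy, pixel_size=pixel_size, stride=stride)
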