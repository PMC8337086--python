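"""Detection, classification, orientation, and tracking of +-1/2 defects.

A topological defect is a point where the director angle is discontinuous.
Its charge is the winding number: the total director rotation accumulated
along a closed loop around the point, divided by 2*pi.  Because the director
is nematic (``theta == theta + pi``) half-integer charges are allowed, and in
elongated-cell monolayers only +-1/2 are observed in practice.

A +1/2 ("comet") defect has a single symmetry axis -- the comet tail, the
side on which the director is radial.  A -1/2 ("trefoil") defect has three
symmetry axes ("legs") separated by 120 degrees.  Near a defect of charge q
and phase theta0 the director follows ``theta(phi) = q*phi + theta0``, so the
axes solve ``(1 - q) * phi == theta0 (mod pi)``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, List, NamedTuple, Optional, Sequence

import numpy as np

from .director import OrientationField, nematic_difference, wrap_nematic

__all__ = [
    "DefectRecord",
    "DefectTrack",
    "RingFit",
    "winding_number",
    "plaquette_charges",
    "detect_defects",
    "ring_phase_fit",
    "defect_axes",
    "track_defects",
]

_HALF = 0.5


@dataclasses.dataclass
class DefectRecord:
    """One detected topological defect.

    ``position`` is ``(x, y)`` in micrometres; ``charge`` is a half-integer
    (+0.5 or -0.5 when resolved); ``phase`` is the director offset theta0 in
    ``[0, pi)``; ``axes`` holds the symmetry-axis directions in radians
    (one entry for +1/2, the tail direction mod 2*pi; three for -1/2).
    """

    frame: int
    position: np.ndarray
    charge: float
    phase: float
    axes: tuple = ()
    core_coherence: float = float("nan")
    flags: tuple = ()

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (2,):
            raise ValueError("position must be a 2-vector (x, y)")


@dataclasses.dataclass
class DefectTrack:
    """Trajectory of one defect across frames."""

    points: list  # [(frame, position array), ...] frames strictly increasing
    charge: float
    mean_speed: float  # path length / elapsed time (um/h)
    net_displacement: float  # |last - first| (um)

    @property
    def frames(self):
        return [f for f, _ in self.points]


class RingFit(NamedTuple):
    """Least-squares fit of the director on a ring to theta = q*phi + theta0."""

    charge: float
    phase: float
    residual: float
    ok: bool


def _wrap_half_diff(d):
    """Wrap angle differences into ``(-pi/2, pi/2]`` (nematic increments)."""
    return np.pi / 2 - np.mod(np.pi / 2 - np.asarray(d, dtype=float), np.pi)


def _round_half_integer(total_rotation: float, tol: float = 1e-6) -> float:
    """Convert a summed rotation (multiple of pi) to a half-integer charge."""
    charge = total_rotation / (2 * np.pi)
    nearest = round(charge * 2) / 2
    if abs(charge - nearest) > tol:
        raise ValueError(
            f"winding {charge} is not a half-integer within tolerance {tol}"
        )
    return nearest


def winding_number(
    field: OrientationField,
    loop: Sequence,
    coherence_floor: float = 0.0,
) -> float:
    """Winding number of the director along a closed loop of grid nodes.

    Successive nematic differences are wrapped into ``(-pi/2, pi/2]``, summed
    around the loop, and divided by 2*pi; the result is an exact multiple of
    1/2 by construction (checked to 1e-6).

    Parameters
    ----------
    loop:
        Ordered sequence of ``(row, col)`` node indices, at least 8 nodes;
        the loop is closed automatically if the last node differs from the
        first.
    coherence_floor:
        If any visited node has coherence below this floor a ``ValueError``
        is raised flagging the loop as unreliable.
    """
    loop = np.asarray(loop, dtype=int)
    if loop.ndim != 2 or loop.shape[1] != 2:
        raise ValueError("loop must be a sequence of (row, col) nodes")
    if np.array_equal(loop[0], loop[-1]):
        loop = loop[:-1]
    if len(loop) < 8:
        raise ValueError("loop must contain at least 8 distinct nodes")
    rows, cols = loop[:, 0], loop[:, 1]
    if coherence_floor > 0:
        coh = field.coherence[rows, cols]
        if np.any(coh < coherence_floor):
            raise ValueError("loop touches a node with coherence below floor; unreliable")
    theta = field.theta[rows, cols]
    d = _wrap_half_diff(np.diff(np.concatenate([theta, theta[:1]])))
    return _round_half_integer(float(d.sum()))


def plaquette_charges(field: OrientationField) -> np.ndarray:
    """Winding number of every 2x2 plaquette, shape ``(ny - 1, nx - 1)``.

    The loop runs counterclockwise in the y-up frame:
    ``(r, c) -> (r, c+1) -> (r+1, c+1) -> (r+1, c) -> (r, c)``.
    """
    t = field.theta
    dx = _wrap_half_diff(t[:, 1:] - t[:, :-1])  # step in +x
    dy = _wrap_half_diff(t[1:, :] - t[:-1, :])  # step in +y
    total = dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]
    return total / (2 * np.pi)


def _ring_points(center, radius: float, n: int):
    phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    x = center[0] + radius * np.cos(phi)
    y = center[1] + radius * np.sin(phi)
    return phi, x, y


def _ring_winding(field: OrientationField, center, radius: float, n: int = 96) -> float:
    """Winding measured on an interpolated circular loop (micrometre coords)."""
    _, x, y = _ring_points(center, radius, n)
    theta, _ = field.sample(x, y)
    d = _wrap_half_diff(np.diff(np.concatenate([theta, theta[:1]])))
    return _round_half_integer(float(d.sum()))


def ring_phase_fit(
    field: OrientationField,
    center,
    radius: float,
    n: int = 96,
    residual_tol: float = 0.5,
) -> RingFit:
    """Fit director samples on a ring to ``theta(phi) = q*phi + theta0``.

    The fit is performed on the doubled angle ``psi = 2*theta`` (which is an
    ordinary circular quantity under nematic symmetry): ``psi`` is unwrapped
    along the ring, its slope gives ``2q``, and the circular mean of
    ``psi - 2*q_rounded*phi`` gives ``2*theta0``.  ``ok`` is False when the
    circular RMS residual exceeds ``residual_tol`` radians (e.g. the ring
    crosses another defect core).
    """
    center = np.asarray(center, dtype=float)
    xmax, ymax = field.extent
    if (center[0] - radius < 0 or center[1] - radius < 0
            or center[0] + radius > xmax or center[1] + radius > ymax):
        raise ValueError("ring must lie entirely inside the field")
    phi, x, y = _ring_points(center, radius, n)
    theta, _ = field.sample(x, y)
    psi = np.unwrap(2 * theta)
    slope = float(np.polyfit(phi, psi, 1)[0])
    charge = slope / 2
    q_round = round(charge * 2) / 2
    resid_phase = psi - 2 * q_round * phi
    psi0 = math.atan2(float(np.mean(np.sin(resid_phase))), float(np.mean(np.cos(resid_phase))))
    theta0 = float(wrap_nematic(psi0 / 2))
    wrapped = np.angle(np.exp(1j * (resid_phase - psi0)))
    residual = float(np.sqrt(np.mean(wrapped**2))) / 2  # back on the theta scale
    return RingFit(charge=charge, phase=theta0, residual=residual, ok=residual <= residual_tol)


def _polarization(field: OrientationField, center, radius: float):
    """Defect polarization p = div Q from the coherence-weighted tensor.

    Averaged over a disc of the given radius (micrometres) around the core.
    For a +1/2 defect p points toward the comet-tail side (the side on which
    the director is radial).
    """
    qxx, qxy = field.nematic_tensor()
    gs = field.grid_spacing
    dqxx_dy, dqxx_dx = np.gradient(qxx, gs)
    dqxy_dy, dqxy_dx = np.gradient(qxy, gs)
    px = dqxx_dx + dqxy_dy
    py = dqxy_dx - (-dqxx_dy)  # Qyy = -Qxx
    xg, yg = field.node_positions()
    mask = (xg - center[0]) ** 2 + (yg - center[1]) ** 2 <= radius**2
    if not mask.any():
        return np.zeros(2)
    return np.array([px[mask].mean(), py[mask].mean()])


def defect_axes(field: OrientationField, record: DefectRecord, ring_radius: Optional[float] = None):
    """Symmetry-axis directions (radians, mod 2*pi) of a defect.

    For charge -1/2 the three legs are ``phi_k = (2/3) * (theta0 + k*pi)``,
    k in {0, 1, 2}, pairwise 120 degrees apart (the set is invariant under
    the nematic ambiguity ``theta0 -> theta0 + pi``).  For charge +1/2 the
    candidate tail directions are ``2*theta0`` and ``2*theta0 + pi``; the
    phase is only defined mod pi, so the tail sign is disambiguated with the
    polarization vector ``p = div Q``: the tail points along +p, the side on
    which the director is radial.
    """
    q, theta0 = record.charge, record.phase
    if ring_radius is None:
        ring_radius = 5 * field.grid_spacing
    if q == -_HALF:
        axes = [(2.0 / 3.0) * (theta0 + k * np.pi) % (2 * np.pi) for k in range(3)]
        return tuple(sorted(axes))
    if q == _HALF:
        p = _polarization(field, record.position, ring_radius)
        candidate = 2 * theta0 % (2 * np.pi)
        if np.linalg.norm(p) > 0 and math.cos(candidate - math.atan2(p[1], p[0])) < 0:
            candidate = (candidate + np.pi) % (2 * np.pi)
        return (candidate,)
    raise ValueError(f"axes are only defined for charge +-1/2, got {q}")


def _cluster(points: np.ndarray, radius: float) -> List[np.ndarray]:
    """Single-linkage clustering of candidate points within ``radius``."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= radius:
                parent[find(i)] = find(j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [np.asarray(v, dtype=int) for v in groups.values()]


def detect_defects(
    field: OrientationField,
    coherence_max: float = 1.0,
    loop_radius: int = 5,
    merge_radius: Optional[float] = None,
    frame: int = 0,
    compute_axes: bool = True,
) -> List[DefectRecord]:
    """Locate and classify topological defects in an orientation field.

    Every 2x2 plaquette with nonzero winding becomes a candidate; candidates
    of equal sign within ``merge_radius`` (micrometres; default 3 grid nodes)
    are clustered and their centroid is the defect position.  The charge is
    re-measured on a circular loop of ``loop_radius`` grid nodes around the
    centroid when it fits inside the field, and the phase is obtained from a
    ring fit.  Records are sorted row-major (y, then x) for determinism.

    Defect cores melt the local order, so candidate plaquettes are also
    required to contain a node with coherence <= ``coherence_max``
    (1.0 disables the gate).  Defects closer than ``2 * loop_radius`` nodes
    are both returned, flagged ``"unresolved neighborhood"``; charges that do
    not resolve to +-1/2 are flagged ``"unresolved"``.
    """
    gs = field.grid_spacing
    if merge_radius is None:
        merge_radius = 3 * gs
    charges = plaquette_charges(field)
    cand = np.argwhere(np.abs(charges) > 0.25)
    if coherence_max < 1.0 and len(cand):
        c = field.coherence
        keep = []
        for r, cc in cand:
            if min(c[r, cc], c[r, cc + 1], c[r + 1, cc], c[r + 1, cc + 1]) <= coherence_max:
                keep.append(True)
            else:
                keep.append(False)
        cand = cand[np.asarray(keep, dtype=bool)]
    records: List[DefectRecord] = []
    if len(cand):
        # plaquette center positions in micrometres, (x, y)
        pos = np.stack([(cand[:, 1] + 0.5) * gs, (cand[:, 0] + 0.5) * gs], axis=1)
        q = charges[cand[:, 0], cand[:, 1]]
        xmax, ymax = field.extent
        for sign in (1.0, -1.0):
            sel = np.where(np.sign(q) == sign)[0]
            if not len(sel):
                continue
            for group in _cluster(pos[sel], merge_radius):
                centroid = pos[sel][group].mean(axis=0)
                charge = float(np.round(q[sel][group].sum() * 2) / 2)
                flags: list = []
                ring_r = loop_radius * gs
                inside = (ring_r <= centroid[0] <= xmax - ring_r
                          and ring_r <= centroid[1] <= ymax - ring_r)
                phase = float("nan")
                if inside:
                    try:
                        charge = _ring_winding(field, centroid, ring_r)
                    except ValueError:
                        flags.append("unresolved")
                    fit = ring_phase_fit(field, centroid, ring_r)
                    phase = fit.phase
                    if not fit.ok:
                        flags.append("poor ring fit")
                else:
                    flags.append("near boundary")
                if charge not in (_HALF, -_HALF):
                    flags.append("unresolved")
                th_core, coh_core = field.sample(centroid[0], centroid[1])
                records.append(
                    DefectRecord(
                        frame=frame,
                        position=centroid,
                        charge=charge,
                        phase=phase,
                        core_coherence=float(coh_core),
                        flags=tuple(flags),
                    )
                )
    # neighbourhood resolution flags
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            if np.linalg.norm(a.position - b.position) < 2 * loop_radius * gs:
                for rec in (a, b):
                    if "unresolved neighborhood" not in rec.flags:
                        rec.flags = rec.flags + ("unresolved neighborhood",)
    if compute_axes:
        for rec in records:
            if rec.charge in (_HALF, -_HALF) and np.isfinite(rec.phase):
                rec.axes = defect_axes(field, rec, ring_radius=loop_radius * gs)
    records.sort(key=lambda r: (r.position[1], r.position[0]))
    return records


def track_defects(
    records_per_frame: Sequence[Sequence[DefectRecord]],
    max_link: float,
    frame_interval: float = 1.0,
) -> List[DefectTrack]:
    """Greedy nearest-neighbour frame-to-frame linking of defects.

    Only same-charge defects within ``max_link`` micrometres are linked;
    unmatched defects start or terminate tracks.  Ties are broken by smallest
    distance, then row-major order of the candidate (deterministic).  Mean
    speed is path length divided by elapsed time (``frame_interval`` hours
    between consecutive frames).
    """
    if max_link <= 0:
        raise ValueError("max_link must be positive")
    open_tracks: List[list] = []  # lists of (frame, record)
    closed: List[list] = []
    for fi, records in enumerate(records_per_frame):
        unmatched = list(range(len(records)))
        candidates = []
        for ti, tr in enumerate(open_tracks):
            last_frame, last_rec = tr[-1]
            if last_frame != fi - 1:
                continue
            for ri in unmatched:
                rec = records[ri]
                if rec.charge != last_rec.charge:
                    continue
                d = float(np.linalg.norm(rec.position - last_rec.position))
                if d <= max_link:
                    candidates.append((d, rec.position[1], rec.position[0], ti, ri))
        used_tracks: set = set()
        used_recs: set = set()
        for d, _, _, ti, ri in sorted(candidates):
            if ti in used_tracks or ri in used_recs:
                continue
            open_tracks[ti].append((fi, records[ri]))
            used_tracks.add(ti)
            used_recs.add(ri)
        still_open = []
        for ti, tr in enumerate(open_tracks):
            if ti in used_tracks or tr[-1][0] == fi:
                still_open.append(tr)
            else:
                closed.append(tr)
        open_tracks = still_open
        for ri in range(len(records)):
            if ri not in used_recs:
                open_tracks.append([(fi, records[ri])])
    closed.extend(open_tracks)

    tracks: List[DefectTrack] = []
    for tr in closed:
        pts = [(f, rec.position.copy()) for f, rec in tr]
        path = sum(
            float(np.linalg.norm(pts[i + 1][1] - pts[i][1])) for i in range(len(pts) - 1)
        )
        elapsed = (pts[-1][0] - pts[0][0]) * frame_interval
        speed = path / elapsed if elapsed > 0 else 0.0
        net = float(np.linalg.norm(pts[-1][1] - pts[0][1]))
        tracks.append(
            DefectTrack(points=pts, charge=tr[0][1].charge, mean_speed=speed, net_displacement=net)
        )
    tracks.sort(key=lambda t: (t.points[0][0], t.points[0][1][1], t.points[0][1][0]))
    return tracks
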