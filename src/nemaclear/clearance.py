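"""Spheroid spread area, cleared area, and mesothelial clearance rates.

A cancer-cell spheroid seeded on a confluent mesothelial layer displaces
("clears") the mesothelial cells over time.  The spheroid footprint and the
cleared region are segmented from the two fluorescence channels; the cleared
area grows approximately linearly, so its OLS slope is the clearance rate
(um^2/h), and dividing by the initial spheroid area gives the normalized
clearance rate (1/h).  Spheroids are classified by their position relative
to nearby topological defects: on the tail side of a +1/2 defect, on or off
the legs of a -1/2 defect (45 um band), or control, using the 750 um
qualification radius.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from . import stats as _stats
from .defects import DefectRecord

__all__ = [
    "ClearanceTrace",
    "segment_area",
    "clearance_rate",
    "normalized_rate",
    "classify_location",
    "group_rates",
    "LOCATION_CLASSES",
]

LOCATION_CLASSES = ("control", "plus_half", "minus_half_on_leg", "minus_half_outside_leg")


@dataclasses.dataclass
class ClearanceTrace:
    """Per-spheroid clearance time series and fitted rates."""

    times: np.ndarray  # hours, strictly increasing
    spheroid_area: np.ndarray  # um^2
    cleared_area: np.ndarray  # um^2
    rate: float = float("nan")  # um^2/h
    normalized_rate: float = float("nan")  # 1/h
    location_class: str = "control"
    r_squared: float = float("nan")
    residual_sd: float = float("nan")
    spheroid_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.spheroid_area = np.asarray(self.spheroid_area, dtype=float)
        self.cleared_area = np.asarray(self.cleared_area, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.spheroid_area < 0) or np.any(self.cleared_area < 0):
            raise ValueError("areas must be non-negative")
        if self.location_class not in LOCATION_CLASSES:
            raise ValueError(f"unknown location class {self.location_class!r}")

    def fit(self) -> "ClearanceTrace":
        """Fit the clearance rate and normalized rate in place."""
        self.rate, self.r_squared, self.residual_sd = clearance_rate(
            self.times, self.cleared_area, full=True
        )
        self.normalized_rate = normalized_rate(self.rate, float(self.spheroid_area[0]))
        return self


def segment_area(
    fluor_image: np.ndarray,
    pixel_size: float,
    min_object_px: int = 25,
):
    """Segment the dominant fluorescent object and measure its area.

    Otsu threshold -> largest connected component of at least
    ``min_object_px`` pixels -> hole filling.  Returns
    ``(mask, area_um2, flagged)``; a blank image yields area 0 with the flag
    set rather than raising.
    """
    img = np.asarray(fluor_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    empty = np.zeros(img.shape, dtype=bool)
    if np.ptp(img) == 0:
        return empty, 0.0, True
    try:
        thr = threshold_otsu(img)
    except ValueError:
        return empty, 0.0, True
    binary = img > thr
    labels, n = ndimage.label(binary)
    if n == 0:
        return empty, 0.0, True
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_object_px:
        return empty, 0.0, True
    mask = ndimage.binary_fill_holes(labels == best)
    area = float(mask.sum()) * pixel_size**2
    return mask, area, False


def clearance_rate(times, cleared_areas, full: bool = False):
    """OLS slope of cleared area vs time (um^2/h).

    With ``full=True`` also returns R^2 and the residual SD.
    """
    times = np.asarray(times, dtype=float)
    areas = np.asarray(cleared_areas, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 time points")
    fit = _stats.linreg_ci(times, areas)
    if not full:
        return fit.slope
    resid_sd = float(np.std(areas - (fit.slope * times + fit.intercept), ddof=2))
    return fit.slope, fit.r_squared, resid_sd


def normalized_rate(rate: float, spheroid_area_t0: float) -> float:
    """Clearance rate divided by the initial spheroid area (1/h)."""
    if spheroid_area_t0 <= 0:
        raise ValueError("initial spheroid area must be positive")
    return rate / spheroid_area_t0


def classify_location(
    spheroid_centroid,
    defect_records: Sequence[DefectRecord],
    qualification_radius: float = 750.0,
    leg_halfwidth: float = 45.0,
) -> str:
    """Classify a spheroid's position relative to nearby defects.

    Within ``qualification_radius`` um of a +1/2 core the spheroid qualifies
    only when its centroid projects positively onto the comet-tail axis;
    within the radius of a -1/2 core it is on-leg when its perpendicular
    distance to any leg ray is at most ``leg_halfwidth``, else outside-leg.
    The nearest qualifying defect wins; exact distance ties go to +1/2.
    Anything else is control.
    """
    c = np.asarray(spheroid_centroid, dtype=float)
    candidates: List[Tuple[float, int, str]] = []  # (distance, priority, class)
    for rec in defect_records:
        d = float(np.linalg.norm(c - rec.position))
        if d > qualification_radius:
            continue
        rel = c - rec.position
        if rec.charge == 0.5:
            if not rec.axes:
                continue
            tail = rec.axes[0]
            if rel @ np.array([np.cos(tail), np.sin(tail)]) > 0:
                candidates.append((d, 0, "plus_half"))
        elif rec.charge == -0.5:
            if len(rec.axes) != 3:
                continue
            on_leg = False
            for leg in rec.axes:
                u = np.array([np.cos(leg), np.sin(leg)])
                proj = rel @ u
                if proj >= 0 and abs(rel[0] * u[1] - rel[1] * u[0]) <= leg_halfwidth:
                    on_leg = True
                    break
            candidates.append((d, 1, "minus_half_on_leg" if on_leg else "minus_half_outside_leg"))
    if not candidates:
        return "control"
    candidates.sort(key=lambda t: (t[0], t[1]))
    return candidates[0][2]


def group_rates(traces: Sequence[ClearanceTrace]) -> dict:
    """Per-class median normalized rates and rank-based group comparison.

    Runs the Kruskal-Wallis omnibus across classes and pairwise rank-sum
    tests versus control with Bonferroni correction (both raw and corrected
    p reported).  With a single class, medians only.
    """
    by_class: Dict[str, List[float]] = {}
    for tr in traces:
        by_class.setdefault(tr.location_class, []).append(tr.normalized_rate)
    medians = {k: float(np.median(v)) for k, v in by_class.items()}
    out = {"medians": medians, "n": {k: len(v) for k, v in by_class.items()},
           "omnibus": None, "pairwise": []}
    eligible = [k for k in LOCATION_CLASSES if len(by_class.get(k, [])) >= 3]
    if len(eligible) >= 2:
        groups = [np.asarray(by_class[k]) for k in eligible]
        out["omnibus"] = _stats.kruskal_wallis(groups)
        if "control" in eligible:
            ci = eligible.index("control")
            results = _stats.pairwise_vs_control(groups, control_index=ci, method="rank_sum")
            others = [k for k in eligible if k != "control"]
            out["pairwise"] = list(zip(others, results))
    return out
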