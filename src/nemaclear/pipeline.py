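"""End-to-end synthetic studies: velocity, density, and clearance.

Each run builds synthetic scenes with planted ground truth, pushes them
through the full measurement chain (texture -> director -> defect detection
-> image correlation -> defect-frame summaries; nuclei -> photometric
density profiles; mask stacks -> segmented areas -> clearance rates), and
writes CSV tables plus a JSON manifest echoing every parameter.  Identical
(config, seed) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from . import stats as _stats
from ._version import __version__
from .clearance import ClearanceTrace, classify_location, group_rates, segment_area
from .defects import DefectRecord, detect_defects
from .density import compare_timepoints, default_radii, density_vs_radius, single_cell_intensity
from .director import OrientationField, estimate_director
from .flow import (VelocityField, minus_half_sectors, piv_displacement, plus_half_boxes,
                   polar_components, rotate_frame)
from .io import write_json
from .synthgen import (PlantedDefect, SceneConfig, advect_image, clearance_scene,
                       defect_flow_field, ideal_director_field, nuclei_image, planted_record,
                       render_cell_texture)

__all__ = ["RunConfig", "run_velocity_study", "run_density_study", "run_clearance_study",
           "run_all"]

_FLOAT_FMT = "%.12g"


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults.

    Spatial defaults: 0.625 um/px so a 16 px correlation spacing is 10 um;
    64x64 px subsets; 500x750 um boxes separated by 50 um; -1/2 sector
    exclusions at 250 um (core), 45 um (leg band), 1800 um (outer); density
    circles from 10 to 350 um; 750 um spheroid qualification radius; hourly
    clearance imaging for 15 h and 10 min velocity frames.
    """

    seed: int = 0
    # imaging geometry
    pixel_size: float = 0.625  # um/px
    frame_interval_velocity: float = 1.0 / 6.0  # h (10 min)
    frame_interval_clearance: float = 1.0  # h
    # director estimation
    gradient_sigma: float = 2.0
    window_sigma: float = 16.0
    director_stride: int = 16
    # PIV
    subset_px: int = 64
    spacing_px: int = 16
    # +1/2 box geometry (um)
    box_w: float = 500.0
    box_h: float = 750.0
    box_gap: float = 50.0
    # -1/2 sector geometry (um)
    r_min: float = 250.0
    leg_halfwidth: float = 45.0
    r_max: float = 1800.0
    # defect-flow template
    v0: float = 10.0  # um/h
    decay_length: float = 200.0  # um
    streak_length: float = 20.0  # um
    control_flow_rms: float = 3.0  # um/h RMS of the random control flow
    # velocity study cohort
    velocity_shape: Tuple[int, int] = (1280, 1792)  # (ny, nx) px
    n_plus: int = 21
    n_minus: int = 9
    n_controls: int = 21
    n_controls_minus: int = 15
    # density study
    density_shape: Tuple[int, int] = (1600, 1600)
    n_plus_density: int = 6
    n_minus_density: int = 3
    base_density: float = 2000.0  # cells/mm^2, confluent monolayer
    density_range: float = 150.0  # um decay of the defect density excess
    plus_excess_t0: float = 0.1
    plus_excess_t1: float = 1.0  # core density doubles by 10 h
    minus_excess_t0: float = -0.5
    minus_excess_t1: float = -0.25
    spot_sigma: float = 5.0  # um
    intensity_per_cell: float = 1000.0
    n_sample_nuclei: int = 15
    radii: Tuple[float, ...] = tuple(float(r) for r in default_radii())
    # clearance study
    clearance_shape: Tuple[int, int] = (256, 256)
    clearance_pixel_size: float = 2.5
    n_frames_clearance: int = 15
    n_per_class: int = 20
    control_norm_rate: float = 0.25  # 1/h, median
    defect_suppression: float = 2.0  # on-defect rates are control / this
    rate_sigma_log: float = 0.5
    spheroid_area0: float = 1.0e4  # um^2, median
    area_sigma_log: float = 0.3
    boundary_noise: float = 0.05
    qualification_radius: float = 750.0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        """Build a config from a dict, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("velocity_shape", "density_shape", "clearance_shape", "radii"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["nemaclear_version"] = __version__
        return d

    def child_seed(self, *tags: int) -> int:
        """Deterministic sub-seed derived from the run seed (< 2**31)."""
        ss = np.random.SeedSequence([int(self.seed)] + [int(t) for t in tags])
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _scene_cfg(cfg: RunConfig, shape, seed: int) -> SceneConfig:
    return SceneConfig(shape=tuple(shape), pixel_size=cfg.pixel_size, seed=seed,
                       frame_interval=cfg.frame_interval_velocity)


def _nearest_detected(records: Sequence[DefectRecord], center, charge: float,
                      max_dist: float) -> Optional[DefectRecord]:
    best, best_d = None, max_dist
    for rec in records:
        if rec.charge != charge:
            continue
        d = float(np.linalg.norm(rec.position - np.asarray(center)))
        if d < best_d:
            best, best_d = rec, d
    return best


def _measured_pair(cfg: RunConfig, scene: SceneConfig, texture: np.ndarray,
                   vel_field_px) -> VelocityField:
    """Advect the texture by the per-pixel velocity field and run PIV."""
    dt = cfg.frame_interval_velocity
    ny, nx = texture.shape
    dx = vel_field_px[0][:ny, :nx] * dt / cfg.pixel_size
    dy = vel_field_px[1][:ny, :nx] * dt / cfg.pixel_size
    warped, _ = advect_image(texture, (dx, dy), max_displacement=cfg.subset_px / 2)
    return piv_displacement(
        texture, warped, subset_px=cfg.subset_px, spacing_px=cfg.spacing_px,
        pixel_size=cfg.pixel_size, frame_interval=dt,
    )


def _control_flow(cfg: RunConfig, scene: SceneConfig):
    """Smooth zero-mean random velocity field (um/h) at pixel resolution."""
    rng = scene.rng(stream=7)
    smooth = 64.0 / cfg.pixel_size  # ~64 um correlation length, in px
    comps = []
    for _ in range(2):
        f = ndimage.gaussian_filter(rng.standard_normal(scene.shape), smooth, mode="wrap")
        f -= f.mean()
        rms = np.sqrt(np.mean(f**2))
        comps.append(f / rms * cfg.control_flow_rms if rms > 0 else f)
    return comps[0], comps[1]


def _defect_row(scene_id: str, kind: str, rec: DefectRecord) -> dict:
    return {
        "scene": scene_id, "kind": kind, "frame": rec.frame,
        "x_um": rec.position[0], "y_um": rec.position[1],
        "charge": rec.charge, "phase_rad": rec.phase,
        "axes_rad": ";".join(_FLOAT_FMT % a for a in rec.axes),
        "core_coherence": rec.core_coherence, "flags": "|".join(rec.flags),
    }


def run_velocity_study(cfg: RunConfig, out_dir) -> dict:
    """Defect-centered velocity analysis on synthetic monolayer movies.

    For each planted +1/2 defect a textured frame pair is generated with the
    inward comet-axis flow template, the director and defect are re-detected
    from the texture, the PIV field is rotated into the detected defect
    frame, and velocities are averaged in the four boxes.  -1/2 scenes use
    the leg-convergent/radially-outward template and the six-sector angular
    and radial averages.  Control scenes carry a smooth zero-mean random
    flow.  Box/sector statistics are compared with controls by one-way ANOVA
    with Bonferroni correction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    center_um = (cfg.velocity_shape[1] * cfg.pixel_size / 2,
                 cfg.velocity_shape[0] * cfg.pixel_size / 2)
    defect_rows: List[dict] = []
    summary_rows: List[dict] = []
    left_vx: List[float] = []
    right_vx: List[float] = []
    a_vphi: List[float] = []
    b_vphi: List[float] = []
    ctrl_vx: List[float] = []
    ctrl_vphi: List[float] = []

    def run_defect_scene(i: int, charge: float):
        scene = _scene_cfg(cfg, cfg.velocity_shape, cfg.child_seed(1, i, int(charge < 0)))
        phase = float(scene.rng(stream=9).uniform(0, np.pi))
        planted = PlantedDefect(position=center_um, charge=charge, phase=phase)
        field = ideal_director_field([planted], scene, stride=cfg.director_stride)
        texture = render_cell_texture(field, cfg.streak_length, scene)
        est = estimate_director(texture, cfg.pixel_size, cfg.gradient_sigma,
                                cfg.window_sigma, stride=cfg.director_stride)
        records = detect_defects(est, loop_radius=5)
        rec = _nearest_detected(records, center_um, charge, max_dist=100.0)
        scene_id = f"{'plus' if charge > 0 else 'minus'}_{i:03d}"
        if rec is None:  # fall back to planted truth, flagged
            rec = planted_record(planted, field)
            rec.flags = rec.flags + ("detection failed; planted truth used",)
        defect_rows.append(_defect_row(scene_id, "defect", rec))
        template = defect_flow_field(planted_record(planted, field), cfg.v0,
                                     cfg.decay_length, scene,
                                     node_spacing=cfg.pixel_size,
                                     leg_halfwidth=cfg.leg_halfwidth)
        measured = _measured_pair(cfg, scene, texture, (template.vx, template.vy))
        if charge > 0:
            tail = rec.axes[0]
            rotated = rotate_frame(measured, rec.position, tail)
            summary = plus_half_boxes(rotated, rec.position, cfg.box_w, cfg.box_h, cfg.box_gap)
            left_vx.append(summary.left.mean_vx)
            right_vx.append(summary.right.mean_vx)
            summary_rows.append({
                "scene": scene_id, "class": "plus_half",
                "vx_left": summary.left.mean_vx, "vx_right": summary.right.mean_vx,
                "vy_top": summary.top.mean_vy, "vy_bottom": summary.bottom.mean_vy,
                "vphi_A": np.nan, "vphi_B": np.nan,
                "vr_on_leg": np.nan, "vr_off_leg": np.nan,
                "tail_rad": tail,
            })
        else:
            summary = minus_half_sectors(measured, rec.position, rec.axes,
                                         r_min=cfg.r_min, leg_halfwidth=cfg.leg_halfwidth,
                                         r_max=cfg.r_max)
            a_vphi.append(summary.mean_vphi_A)
            b_vphi.append(summary.mean_vphi_B)
            summary_rows.append({
                "scene": scene_id, "class": "minus_half",
                "vx_left": np.nan, "vx_right": np.nan,
                "vy_top": np.nan, "vy_bottom": np.nan,
                "vphi_A": summary.mean_vphi_A, "vphi_B": summary.mean_vphi_B,
                "vr_on_leg": summary.mean_vr_on_leg, "vr_off_leg": summary.mean_vr_off_leg,
                "tail_rad": np.nan,
            })

    for i in range(cfg.n_plus):
        run_defect_scene(i, +0.5)
    for i in range(cfg.n_minus):
        run_defect_scene(i, -0.5)

    n_ctrl = max(cfg.n_controls, cfg.n_controls_minus)
    for i in range(n_ctrl):
        scene = _scene_cfg(cfg, cfg.velocity_shape, cfg.child_seed(2, i))
        angle = float(scene.rng(stream=9).uniform(0, np.pi))
        theta = np.full(scene.shape, angle)
        field = OrientationField(theta=theta, coherence=np.ones_like(theta),
                                 grid_spacing=cfg.pixel_size, pixel_size=cfg.pixel_size)
        texture = render_cell_texture(field, cfg.streak_length, scene)
        flow_px = _control_flow(cfg, scene)
        measured = _measured_pair(cfg, scene, texture, flow_px)
        scene_id = f"control_{i:03d}"
        if i < cfg.n_controls:
            summary = plus_half_boxes(measured, center_um, cfg.box_w, cfg.box_h, cfg.box_gap)
            ctrl_vx.append(0.5 * (summary.left.mean_vx + summary.right.mean_vx))
        if i < cfg.n_controls_minus:
            rng = scene.rng(stream=10)
            legs = tuple(float(rng.uniform(0, 2 * np.pi / 3) + k * 2 * np.pi / 3)
                         for k in range(3))
            sectors = minus_half_sectors(measured, center_um, legs, r_min=cfg.r_min,
                                         leg_halfwidth=cfg.leg_halfwidth, r_max=cfg.r_max)
            vals = [v for v in (sectors.mean_vphi_A, sectors.mean_vphi_B)
                    if np.isfinite(v)]
            if vals:
                ctrl_vphi.append(float(np.mean(vals)))
        summary_rows.append({
            "scene": scene_id, "class": "control",
            "vx_left": np.nan, "vx_right": np.nan, "vy_top": np.nan, "vy_bottom": np.nan,
            "vphi_A": np.nan, "vphi_B": np.nan, "vr_on_leg": np.nan, "vr_off_leg": np.nan,
            "tail_rad": np.nan,
        })

    stats_rows: List[dict] = []

    def add_anova(label: str, names: List[str], groups: List[List[float]]):
        groups = [list(g) for g in groups]
        if any(len(g) < 2 for g in groups):
            return
        results = _stats.anova_bonferroni(groups)
        stats_rows.append({
            "analysis": label, "comparison": "omnibus", "method": results[0].method,
            "statistic": results[0].statistic, "p_raw": results[0].p, "p": results[0].p,
            "n": "/".join(str(n) for n in results[0].n),
        })
        import itertools as _it
        for (i, j), res in zip(_it.combinations(range(len(groups)), 2), results[1:]):
            stats_rows.append({
                "analysis": label, "comparison": f"{names[i]} vs {names[j]}",
                "method": res.method, "statistic": res.statistic,
                "p_raw": res.p_raw, "p": res.p,
                "n": "/".join(str(n) for n in res.n),
            })

    add_anova("plus_half_vx", ["control", "left", "right"], [ctrl_vx, left_vx, right_vx])
    add_anova("minus_half_vphi", ["control", "A", "B"], [ctrl_vphi, a_vphi, b_vphi])

    _write_csv(pd.DataFrame(defect_rows, columns=[
        "scene", "kind", "frame", "x_um", "y_um", "charge", "phase_rad", "axes_rad",
        "core_coherence", "flags"]), out_dir / "defects.csv")
    _write_csv(pd.DataFrame(summary_rows, columns=[
        "scene", "class", "vx_left", "vx_right", "vy_top", "vy_bottom",
        "vphi_A", "vphi_B", "vr_on_leg", "vr_off_leg", "tail_rad"]),
        out_dir / "velocity_summary.csv")
    _write_csv(pd.DataFrame(stats_rows, columns=[
        "analysis", "comparison", "method", "statistic", "p_raw", "p", "n"]),
        out_dir / "stats.csv")
    write_json(out_dir / "manifest.json", {"study": "velocity", "config": cfg.manifest()})
    return {
        "n_defect_scenes": cfg.n_plus + cfg.n_minus,
        "left_vx": left_vx, "right_vx": right_vx,
        "vphi_A": a_vphi, "vphi_B": b_vphi,
        "control_vx": ctrl_vx, "control_vphi": ctrl_vphi,
        "stats": stats_rows,
    }


def _density_fn(base: float, excess: float, center, length: float):
    def fn(x, y):
        r = np.hypot(np.asarray(x, dtype=float) - center[0],
                     np.asarray(y, dtype=float) - center[1])
        return base * np.maximum(1.0 + excess * np.exp(-r / length), 0.0)
    return fn


def run_density_study(cfg: RunConfig, out_dir) -> dict:
    """Cell-density profiles around defects at two time points 10 h apart.

    Nuclei are planted with a defect-centered density excess (+1/2 scenes
    accumulate cells by 10 h; -1/2 scenes stay depleted), the single-cell
    intensity is calibrated from 15 random nuclei, and cumulative density
    profiles over R = 10-350 um are fitted by linear regression, pooling
    defects per time point.  Smallest-R densities at the two times are
    compared by rank sum.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ny, nx = cfg.density_shape
    center = (nx * cfg.pixel_size / 2, ny * cfg.pixel_size / 2)
    radii = np.asarray(cfg.radii, dtype=float)
    profile_rows: List[dict] = []
    stats_rows: List[dict] = []
    small_r: Dict[Tuple[str, str], List[float]] = {}
    pooled: Dict[Tuple[str, str], List[np.ndarray]] = {}
    slopes: Dict[Tuple[str, str], tuple] = {}

    plan = [("plus", cfg.n_plus_density, {"t0": cfg.plus_excess_t0, "t10": cfg.plus_excess_t1}),
            ("minus", cfg.n_minus_density, {"t0": cfg.minus_excess_t0, "t10": cfg.minus_excess_t1})]
    for kind, n_defects, excesses in plan:
        for tp, excess in excesses.items():
            for i in range(n_defects):
                scene = SceneConfig(shape=cfg.density_shape, pixel_size=cfg.pixel_size,
                                    seed=cfg.child_seed(3, 0 if kind == "plus" else 1,
                                                        0 if tp == "t0" else 1, i))
                img, _ = nuclei_image(
                    _density_fn(cfg.base_density, excess, center, cfg.density_range),
                    cfg.spot_sigma, cfg.intensity_per_cell, scene)
                cell_int = single_cell_intensity(
                    img, n_sample=cfg.n_sample_nuclei, seed=cfg.child_seed(4, i),
                    integration_radius_px=int(round(4 * cfg.spot_sigma / cfg.pixel_size)))
                profile = density_vs_radius(img, center, radii, cell_int, cfg.pixel_size,
                                            label=f"{kind}_{tp}_{i:02d}")
                key = (kind, tp)
                small_r.setdefault(key, []).append(float(profile.density[0]))
                pooled.setdefault(key, []).append(profile.density)
                for r, c, d in zip(profile.radii, profile.count_est, profile.density):
                    profile_rows.append({
                        "scene": profile.label, "kind": kind, "timepoint": tp,
                        "R_um": r, "count_est": c, "density_cells_mm2": d,
                    })
    for key, dens_list in sorted(pooled.items()):
        x = np.tile(radii, len(dens_list))
        y = np.concatenate(dens_list)
        fit = _stats.linreg_ci(x, y)
        slopes[key] = (fit.slope, fit.slope_ci)
        stats_rows.append({
            "analysis": f"density_slope_{key[0]}_{key[1]}", "comparison": "slope",
            "method": "OLS", "statistic": fit.slope,
            "p_raw": np.nan, "p": np.nan,
            "ci_lo": fit.slope_ci[0], "ci_hi": fit.slope_ci[1],
            "n": str(len(y)),
        })
    for kind in ("plus", "minus"):
        k0, k1 = (kind, "t0"), (kind, "t10")
        if k0 in small_r and k1 in small_r and min(len(small_r[k0]), len(small_r[k1])) >= 3:
            res = compare_timepoints(small_r[k0], small_r[k1])
            stats_rows.append({
                "analysis": f"density_smallR_{kind}", "comparison": "t0 vs t10",
                "method": res.method, "statistic": res.statistic,
                "p_raw": res.p, "p": res.p, "ci_lo": np.nan, "ci_hi": np.nan,
                "n": "/".join(str(n) for n in res.n),
            })
    _write_csv(pd.DataFrame(profile_rows, columns=[
        "scene", "kind", "timepoint", "R_um", "count_est", "density_cells_mm2"]),
        out_dir / "density_profiles.csv")
    _write_csv(pd.DataFrame(stats_rows, columns=[
        "analysis", "comparison", "method", "statistic", "p_raw", "p",
        "ci_lo", "ci_hi", "n"]), out_dir / "stats.csv")
    write_json(out_dir / "manifest.json", {"study": "density", "config": cfg.manifest()})
    return {"slopes": slopes, "small_r": small_r, "stats": stats_rows}


def _dish_defects(cfg: RunConfig) -> List[DefectRecord]:
    """Planted defect layout of the synthetic clearance dish."""
    plus = DefectRecord(frame=0, position=np.array([2000.0, 2000.0]), charge=0.5,
                        phase=0.0, axes=(0.0,))
    minus = DefectRecord(frame=0, position=np.array([8000.0, 2000.0]), charge=-0.5,
                         phase=0.0, axes=(0.0, 2 * np.pi / 3, 4 * np.pi / 3))
    return [plus, minus]


def run_clearance_study(cfg: RunConfig, out_dir) -> dict:
    """Spheroid clearance rates at and away from defects.

    Spheroids with planted normalized clearance rates (control median
    ``control_norm_rate``; on-defect classes suppressed by
    ``defect_suppression``) are rendered as two-channel mask movies,
    re-measured by segmentation, classified by position relative to the
    planted defects, and compared by Kruskal-Wallis with Bonferroni-
    corrected rank-sum tests versus control.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dish = _dish_defects(cfg)
    plus, minus = dish
    rng = np.random.default_rng(cfg.child_seed(5))
    placements = {
        "control": lambda: np.array([12000.0, 12000.0]) + rng.uniform(-500, 500, 2),
        "plus_half": lambda: plus.position + _radial(rng, 150, 600, -np.pi / 3, np.pi / 3),
        "minus_half_on_leg": lambda: minus.position
        + rng.uniform(150, 600) * np.array([1.0, 0.0]) + np.array([0.0, rng.uniform(-30, 30)]),
        "minus_half_outside_leg": lambda: minus.position
        + _radial(rng, 200, 600, np.pi / 3 - 0.3, np.pi / 3 + 0.3),
    }
    suppressed = {"plus_half", "minus_half_on_leg"}
    trace_rows: List[dict] = []
    traces: List[ClearanceTrace] = []
    planted_rows: List[dict] = []
    sid = 0
    for klass in ("control", "plus_half", "minus_half_on_leg", "minus_half_outside_leg"):
        for i in range(cfg.n_per_class):
            sid += 1
            norm_rate = cfg.control_norm_rate * float(np.exp(rng.normal(0, cfg.rate_sigma_log)))
            if klass in suppressed:
                norm_rate /= cfg.defect_suppression
            area0 = cfg.spheroid_area0 * float(np.exp(rng.normal(0, cfg.area_sigma_log)))
            rate = norm_rate * area0
            scene = SceneConfig(shape=cfg.clearance_shape,
                                pixel_size=cfg.clearance_pixel_size,
                                seed=cfg.child_seed(6, sid), frame_interval=1.0)
            stack, table = clearance_scene(area0, rate, cfg.n_frames_clearance, scene,
                                           boundary_noise=cfg.boundary_noise,
                                           frame_interval=cfg.frame_interval_clearance)
            sph_areas = []
            clr_areas = []
            for f in range(stack.shape[0]):
                _, a_sph, _ = segment_area(stack[f, 0], cfg.clearance_pixel_size)
                _, a_clr, _ = segment_area(stack[f, 1], cfg.clearance_pixel_size)
                sph_areas.append(a_sph)
                clr_areas.append(a_clr)
            centroid = placements[klass]()
            measured_class = classify_location(centroid, dish,
                                               qualification_radius=cfg.qualification_radius,
                                               leg_halfwidth=cfg.leg_halfwidth)
            trace = ClearanceTrace(
                times=table["time_h"].to_numpy(), spheroid_area=np.array(sph_areas),
                cleared_area=np.array(clr_areas), location_class=measured_class,
                spheroid_id=f"sph_{sid:03d}",
            ).fit()
            traces.append(trace)
            planted_rows.append({"spheroid": trace.spheroid_id, "intended_class": klass,
                                 "planted_norm_rate": norm_rate, "planted_area0": area0})
            for t, a_s, a_c in zip(trace.times, trace.spheroid_area, trace.cleared_area):
                trace_rows.append({
                    "spheroid": trace.spheroid_id, "class": trace.location_class,
                    "time_h": t, "spheroid_area_um2": a_s, "cleared_area_um2": a_c,
                    "rate_um2_h": trace.rate, "normalized_rate_h": trace.normalized_rate,
                    "r_squared": trace.r_squared,
                })
    summary = group_rates(traces)
    stats_rows: List[dict] = []
    for klass, med in sorted(summary["medians"].items()):
        stats_rows.append({"analysis": "clearance", "comparison": f"median {klass}",
                           "method": "median", "statistic": med, "p_raw": np.nan,
                           "p": np.nan, "n": str(summary["n"][klass])})
    if summary["omnibus"] is not None:
        res = summary["omnibus"]
        stats_rows.append({"analysis": "clearance", "comparison": "omnibus",
                           "method": res.method, "statistic": res.statistic,
                           "p_raw": res.p, "p": res.p,
                           "n": "/".join(str(n) for n in res.n)})
    for klass, res in summary["pairwise"]:
        stats_rows.append({"analysis": "clearance", "comparison": f"{klass} vs control",
                           "method": res.method, "statistic": res.statistic,
                           "p_raw": res.p_raw, "p": res.p,
                           "n": "/".join(str(n) for n in res.n)})
    _write_csv(pd.DataFrame(trace_rows, columns=[
        "spheroid", "class", "time_h", "spheroid_area_um2", "cleared_area_um2",
        "rate_um2_h", "normalized_rate_h", "r_squared"]),
        out_dir / "clearance_traces.csv")
    _write_csv(pd.DataFrame(planted_rows, columns=[
        "spheroid", "intended_class", "planted_norm_rate", "planted_area0"]),
        out_dir / "planted_rates.csv")
    _write_csv(pd.DataFrame(stats_rows, columns=[
        "analysis", "comparison", "method", "statistic", "p_raw", "p", "n"]),
        out_dir / "stats.csv")
    write_json(out_dir / "manifest.json", {"study": "clearance", "config": cfg.manifest()})
    return {"traces": traces, "summary": summary, "stats": stats_rows}


def _radial(rng, r_lo, r_hi, phi_lo, phi_hi):
    r = rng.uniform(r_lo, r_hi)
    phi = rng.uniform(phi_lo, phi_hi)
    return r * np.array([np.cos(phi), np.sin(phi)])


def run_all(cfg: RunConfig, out_dir) -> dict:
    """Run the velocity, density, and clearance studies into subdirectories."""
    out_dir = Path(out_dir)
    return {
        "velocity": run_velocity_study(cfg, out_dir / "velocity"),
        "density": run_density_study(cfg, out_dir / "density"),
        "clearance": run_clearance_study(cfg, out_dir / "clearance"),
    }
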