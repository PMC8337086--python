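"""Defect detection, winding numbers, axes, and tracking."""

import numpy as np
import pytest

from conftest import rectangle_loop, uniform_field
from nemaclear.defects import (DefectRecord, defect_axes, detect_defects, ring_phase_fit,
                               track_defects, winding_number)
from nemaclear.synthgen import PlantedDefect, SceneConfig, ideal_director_field


def unwrap_winding_oracle(thetas):
    """Brute-force oracle: unwrap the director along the loop step by step.

    Each successive angle is shifted by the multiple of pi that brings it
    closest to its predecessor; the winding is the total accumulated change
    around the closed loop divided by 2*pi.
    """
    unwrapped = [float(thetas[0])]
    for t in list(thetas[1:]) + [float(thetas[0])]:
        prev = unwrapped[-1]
        k = round((prev - t) / np.pi)
        unwrapped.append(t + k * np.pi)
    return (unwrapped[-1] - unwrapped[0]) / (2 * np.pi)


def test_winding_on_planted_charges(plus_field, minus_field):
    loop = rectangle_loop(100, 100, 400, 400)
    assert winding_number(plus_field, loop) == +0.5
    assert winding_number(minus_field, loop) == -0.5


def test_winding_zero_without_enclosed_defect(plus_field):
    loop = rectangle_loop(10, 10, 100, 100)  # defect is at node (256, 256)
    assert winding_number(plus_field, loop) == 0.0
    assert winding_number(uniform_field(0.9, (64, 64)), rectangle_loop(5, 5, 50, 50)) == 0.0


def test_winding_of_dipole_pair_cancels(scene512):
    xm, ym = scene512.extent
    pair = [PlantedDefect((xm / 2 - 50, ym / 2), +0.5, 0.0),
            PlantedDefect((xm / 2 + 50, ym / 2), -0.5, 0.0)]
    field = ideal_director_field(pair, scene512)
    loop = rectangle_loop(50, 50, 460, 460)
    w = winding_number(field, loop)
    thetas = field.theta[tuple(np.array(loop).T)]
    assert w == unwrap_winding_oracle(thetas) == 0.0


def test_winding_agrees_with_unwrap_oracle_on_random_fields():
    rng = np.random.default_rng(17)
    from scipy import ndimage

    for _ in range(25):
        z = ndimage.gaussian_filter(rng.standard_normal((96, 96)), 6.0) \
            + 1j * ndimage.gaussian_filter(rng.standard_normal((96, 96)), 6.0)
        field = uniform_field(0.0, (96, 96))
        field.theta = np.mod(np.angle(z) / 2, np.pi)
        loop = rectangle_loop(8, 8, 88, 88)
        thetas = field.theta[tuple(np.array(loop).T)]
        assert winding_number(field, loop) == pytest.approx(
            unwrap_winding_oracle(thetas), abs=1e-9)


def test_winding_validates_loop(plus_field):
    with pytest.raises(ValueError):
        winding_number(plus_field, [(0, 0), (0, 1), (1, 1)])  # too short


def test_detect_single_planted_defect(plus_field, scene512):
    recs = detect_defects(plus_field)
    assert len(recs) == 1
    rec = recs[0]
    xm, ym = scene512.extent
    assert rec.charge == +0.5
    assert np.linalg.norm(rec.position - [xm / 2, ym / 2]) < plus_field.grid_spacing
    assert rec.phase == pytest.approx(0.3, abs=0.02)
    assert rec.flags == ()


def test_detect_uniform_field_is_empty():
    assert detect_defects(uniform_field(1.0, (128, 128))) == []


def test_detect_dipole_pair(scene512):
    xm, ym = scene512.extent
    sep = 100 * scene512.pixel_size
    pair = [PlantedDefect((xm / 2 - sep / 2, ym / 2), +0.5, 0.2),
            PlantedDefect((xm / 2 + sep / 2, ym / 2), -0.5, 0.9)]
    field = ideal_director_field(pair, scene512)
    recs = detect_defects(field)
    assert sorted(r.charge for r in recs) == [-0.5, +0.5]
    for rec, planted in zip(sorted(recs, key=lambda r: r.position[0]), pair):
        assert np.linalg.norm(rec.position - planted.position) < 2 * field.grid_spacing


def test_charge_conservation_inside_loops(scene512):
    """Winding on any loop equals the sum of planted charges it encloses."""
    xm, ym = scene512.extent
    defects = [PlantedDefect((80.0, 80.0), +0.5, 0.1),
               PlantedDefect((240.0, 90.0), -0.5, 0.5),
               PlantedDefect((160.0, 250.0), +0.5, 1.2)]
    field = ideal_director_field(defects, scene512)
    gs = field.grid_spacing
    rng = np.random.default_rng(5)
    for _ in range(20):
        r0, c0 = rng.integers(5, 200, 2)
        r1 = int(rng.integers(r0 + 20, 500))
        c1 = int(rng.integers(c0 + 20, 500))
        enclosed = sum(
            d.charge for d in defects
            if c0 * gs < d.position[0] < c1 * gs and r0 * gs < d.position[1] < r1 * gs
        )
        near_edge = any(
            min(abs(d.position[0] - c * gs) for c in (c0, c1)) < 3 * gs
            or min(abs(d.position[1] - r * gs) for r in (r0, r1)) < 3 * gs
            for d in defects
        )
        if near_edge:
            continue
        assert winding_number(field, rectangle_loop(r0, c0, r1, c1)) == enclosed


def test_gauge_invariance_adding_pi(minus_field):
    shifted = ideal_director_field(minus_field.meta["planted"],
                                   SceneConfig(shape=(512, 512), seed=11))
    shifted.theta = np.mod(shifted.theta + np.pi, np.pi)
    recs_a = detect_defects(minus_field)
    recs_b = detect_defects(shifted)
    assert len(recs_a) == len(recs_b) == 1
    assert recs_a[0].charge == recs_b[0].charge
    assert np.allclose(recs_a[0].position, recs_b[0].position)
    assert recs_a[0].phase == pytest.approx(recs_b[0].phase, abs=1e-9)


@pytest.mark.parametrize("charge,phase", [(+0.5, 0.3), (-0.5, 1.0)])
def test_ring_phase_fit_recovers_planted_parameters(scene512, charge, phase):
    xm, ym = scene512.extent
    field = ideal_director_field([PlantedDefect((xm / 2, ym / 2), charge, phase)], scene512)
    fit = ring_phase_fit(field, (xm / 2, ym / 2), radius=40.0)
    assert fit.charge == pytest.approx(charge, abs=0.02)
    assert fit.phase == pytest.approx(phase, abs=0.05)
    assert fit.ok


def test_ring_phase_fit_on_uniform_field():
    field = uniform_field(0.8, (128, 128), spacing=1.0)
    fit = ring_phase_fit(field, (64.0, 64.0), radius=20.0)
    assert abs(fit.charge) < 0.02


def test_ring_phase_fit_requires_ring_inside(plus_field):
    with pytest.raises(ValueError):
        ring_phase_fit(plus_field, (5.0, 5.0), radius=40.0)


def test_minus_half_axes_are_three_legs_120_apart(minus_field):
    rec = detect_defects(minus_field)[0]
    axes = np.degrees(rec.axes)
    assert len(axes) == 3
    seps = np.diff(np.concatenate([np.sort(axes), [np.sort(axes)[0] + 360]]))
    assert np.allclose(seps, 120.0, atol=1e-6)


def test_minus_half_axes_zero_phase():
    scene = SceneConfig(shape=(512, 512), seed=4)
    xm, ym = scene.extent
    field = ideal_director_field([PlantedDefect((xm / 2, ym / 2), -0.5, 0.0)], scene)
    rec = detect_defects(field)[0]
    assert np.allclose(np.sort(np.degrees(rec.axes)), [0.0, 120.0, 240.0], atol=1.0)


def test_plus_half_has_single_tail_axis_where_director_is_radial(plus_field, scene512):
    rec = detect_defects(plus_field)[0]
    assert len(rec.axes) == 1
    tail = rec.axes[0]
    assert tail == pytest.approx(2 * 0.3, abs=0.05)
    # the director along the tail direction is radial ...
    xm, ym = scene512.extent
    th_tail, _ = plus_field.sample(xm / 2 + 60 * np.cos(tail), ym / 2 + 60 * np.sin(tail))
    from nemaclear.director import nematic_difference

    assert abs(nematic_difference(th_tail, tail)) < 0.05
    # ... and perpendicular to the radius on the opposite (head) side
    th_head, _ = plus_field.sample(xm / 2 - 60 * np.cos(tail), ym / 2 - 60 * np.sin(tail))
    assert abs(abs(nematic_difference(th_head, tail)) - np.pi / 2) < 0.05


def test_axes_rotate_with_the_field(scene512):
    """Rotating the scene by alpha rotates every axis by alpha.

    For the planted construction, a rigid rotation by alpha maps a defect of
    phase theta0 to one of phase theta0 + (1 - q) * alpha.
    """
    xm, ym = scene512.extent
    alpha = 0.7
    for q in (+0.5, -0.5):
        f1 = ideal_director_field([PlantedDefect((xm / 2, ym / 2), q, 0.4)], scene512)
        phase2 = np.mod(0.4 + (1 - q) * alpha, np.pi)
        f2 = ideal_director_field([PlantedDefect((xm / 2, ym / 2), q, phase2)], scene512)
        a1 = np.sort(np.mod(np.asarray(detect_defects(f1)[0].axes) + alpha, 2 * np.pi))
        a2 = np.sort(np.asarray(detect_defects(f2)[0].axes))
        assert np.allclose(a1, a2, atol=0.02)


def test_axes_reject_unknown_charge(plus_field):
    rec = DefectRecord(0, [10.0, 10.0], 0.5, 0.1)
    rec.charge = 1.0
    with pytest.raises(ValueError):
        defect_axes(plus_field, rec)


def test_detection_recall_degrades_with_noise():
    """Recall is perfect on clean fields and does not improve with noise."""
    recalls = []
    for noise in (0.0, 0.15, 0.45):
        hits = 0
        for seed in range(5):
            scene = SceneConfig(shape=(256, 256), seed=seed, director_noise=noise)
            xm, ym = scene.extent
            field = ideal_director_field([PlantedDefect((xm / 2, ym / 2), 0.5, 0.2)], scene)
            recs = [r for r in detect_defects(field)
                    if np.linalg.norm(r.position - [xm / 2, ym / 2]) < 20 and r.charge == 0.5]
            hits += bool(recs)
        recalls.append(hits / 5)
    assert recalls[0] == 1.0
    assert recalls[0] >= recalls[1] >= recalls[2] or recalls[1] == recalls[2] == 1.0


def _record(frame, x, y, charge=0.5):
    return DefectRecord(frame=frame, position=[x, y], charge=charge, phase=0.0)


def test_track_stationary_defect():
    frames = [[_record(f, 100.0, 100.0)] for f in range(10)]
    tracks = track_defects(frames, max_link=20.0, frame_interval=1.0)
    assert len(tracks) == 1
    assert tracks[0].mean_speed == 0.0
    assert tracks[0].net_displacement == 0.0
    assert tracks[0].frames == list(range(10))


def test_track_constant_drift_speed():
    frames = [[_record(f, 100.0 + f, 50.0)] for f in range(8)]
    tracks = track_defects(frames, max_link=5.0, frame_interval=1.0)
    assert len(tracks) == 1
    assert tracks[0].mean_speed == pytest.approx(1.0)
    assert tracks[0].net_displacement == pytest.approx(7.0)


def test_track_terminates_beyond_max_link():
    frames = [
        [_record(0, 0.0, 0.0), _record(0, 500.0, 0.0)],
        [_record(1, 500.0, 0.0), _record(1, 0.0, 0.0)],
    ]
    tracks = track_defects(frames, max_link=50.0, frame_interval=1.0)
    # stationary interpretations link; no track jumps 500 um
    assert all(t.net_displacement <= 50.0 for t in tracks)
    assert len(tracks) == 2


def test_track_ignores_opposite_charges():
    frames = [[_record(0, 0.0, 0.0, +0.5)], [_record(1, 1.0, 0.0, -0.5)]]
    tracks = track_defects(frames, max_link=10.0)
    assert len(tracks) == 2
    assert all(t.net_displacement <= 1e-12 for t in tracks)
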