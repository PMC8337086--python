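"""PIV, frame rotation, polar decomposition, box and sector summaries."""

import numpy as np
import pytest

from nemaclear.flow import (VelocityField, control_summary, minus_half_sectors,
                            piv_displacement, plus_half_boxes, polar_components,
                            rotate_frame)
from nemaclear.synthgen import (PlantedDefect, SceneConfig, ideal_director_field,
                                planted_record, defect_flow_field, render_cell_texture)
from conftest import uniform_field


@pytest.fixture(scope="module")
def textures():
    cfg = SceneConfig(shape=(512, 512), seed=21)
    streaky = render_cell_texture(uniform_field(0.6, cfg.shape, cfg.pixel_size), 20.0, cfg)
    sharp = render_cell_texture(uniform_field(0.6, cfg.shape, cfg.pixel_size),
                                2 * cfg.pixel_size, cfg)
    return streaky, sharp


def test_integer_circular_shift_recovered_exactly(textures):
    _, sharp = textures
    shifted = np.roll(sharp, (2, 3), axis=(0, 1))  # +2 rows (y), +3 cols (x)
    vel = piv_displacement(sharp, shifted, pixel_size=1.0, frame_interval=1.0)
    assert vel.mask.all()
    assert np.abs(vel.vx - 3.0).max() < 0.05
    assert np.abs(vel.vy - 2.0).max() < 0.05


def test_identical_images_give_zero_field(textures):
    streaky, _ = textures
    vel = piv_displacement(streaky, streaky, pixel_size=1.0, frame_interval=1.0)
    # single-precision correlation: zero up to FFT round-off
    assert np.abs(vel.vx).max() < 1e-4 and np.abs(vel.vy).max() < 1e-4


def test_constant_subsets_are_masked_not_fatal():
    a = np.zeros((256, 256))
    a[:, 128:] = np.random.default_rng(0).standard_normal((256, 128))
    vel = piv_displacement(a, a.copy(), pixel_size=1.0, frame_interval=1.0)
    assert not vel.mask.all() and vel.mask.any()


def test_physical_units_of_recovered_velocity(textures):
    """A 3 px shift at 0.625 um/px over 10 min is 11.25 um/h."""
    from nemaclear.synthgen import advect_image

    streaky, _ = textures
    warped, _ = advect_image(streaky, (3.0, 0.0))
    vel = piv_displacement(streaky, warped, pixel_size=0.625, frame_interval=1.0 / 6.0)
    assert vel.vx[vel.mask].mean() == pytest.approx(11.25, abs=0.75)


def test_piv_shape_validation():
    with pytest.raises(ValueError):
        piv_displacement(np.zeros((64, 64)), np.zeros((64, 64)))
    with pytest.raises(ValueError):
        piv_displacement(np.zeros((256, 256)), np.zeros((128, 128)))


def _uniform_velocity(vx, vy, n=81, gs=10.0):
    return VelocityField(vx=np.full((n, n), float(vx)), vy=np.full((n, n), float(vy)),
                         grid_spacing=gs, frame_interval=1.0)


def test_rotate_frame_identity_when_tail_along_x():
    f = _uniform_velocity(2.0, -1.0)
    r = rotate_frame(f, (400.0, 400.0), 0.0)
    sel = r.mask
    assert np.allclose(r.vx[sel], 2.0, atol=1e-9)
    assert np.allclose(r.vy[sel], -1.0, atol=1e-9)


def test_rotate_frame_rotates_vectors():
    f = _uniform_velocity(1.0, 0.0)
    r = rotate_frame(f, (400.0, 400.0), -np.pi / 2)
    assert np.allclose(r.vx[r.mask], 0.0, atol=1e-9)
    assert np.allclose(r.vy[r.mask], 1.0, atol=1e-9)


def test_rotate_frame_round_trip():
    rng = np.random.default_rng(1)
    f = VelocityField(vx=rng.standard_normal((81, 81)), vy=rng.standard_normal((81, 81)),
                      grid_spacing=10.0, frame_interval=1.0)
    from scipy import ndimage

    f.vx = ndimage.gaussian_filter(f.vx, 4.0)
    f.vy = ndimage.gaussian_filter(f.vy, 4.0)
    once = rotate_frame(f, (400.0, 400.0), np.pi)
    twice = rotate_frame(once, (400.0, 400.0), np.pi)
    sel = twice.mask & f.mask
    assert np.abs(twice.vx[sel] - f.vx[sel]).max() < 0.02
    assert np.abs(twice.vy[sel] - f.vy[sel]).max() < 0.02


def test_polar_components_energy_split_and_rigid_rotation():
    n, gs = 101, 10.0
    xg, yg = np.meshgrid(np.arange(n) * gs, np.arange(n) * gs)
    cx = cy = (n - 1) * gs / 2
    omega = 0.01
    f = VelocityField(vx=-omega * (yg - cy), vy=omega * (xg - cx),
                      grid_spacing=gs, frame_interval=1.0)
    v_r, v_phi, ok = polar_components(f, (cx, cy))
    r = np.hypot(xg - cx, yg - cy)
    assert np.abs(v_r[ok]).max() < 1e-9
    assert np.allclose(v_phi[ok], omega * r[ok], atol=1e-9)
    assert np.allclose((v_r**2 + v_phi**2)[ok], (f.vx**2 + f.vy**2)[ok], atol=1e-9)


def test_polar_components_pure_radial_outflow():
    n, gs = 81, 10.0
    xg, yg = np.meshgrid(np.arange(n) * gs, np.arange(n) * gs)
    cx = cy = (n - 1) * gs / 2
    r = np.hypot(xg - cx, yg - cy)
    with np.errstate(invalid="ignore"):
        f = VelocityField(vx=np.where(r > 0, (xg - cx) / np.maximum(r, 1), 0.0),
                          vy=np.where(r > 0, (yg - cy) / np.maximum(r, 1), 0.0),
                          grid_spacing=gs, frame_interval=1.0)
    v_r, v_phi, ok = polar_components(f, (cx, cy))
    assert np.abs(v_phi[ok]).max() < 1e-9
    assert v_r[ok].min() > 0


def _plus_template(v0=10.0, lam=500.0, n=241, gs=10.0):
    xg, yg = np.meshgrid(np.arange(n) * gs, np.arange(n) * gs)
    cx = cy = (n - 1) * gs / 2
    r = np.hypot(xg - cx, yg - cy)
    vx = -v0 * np.sign(xg - cx) * np.exp(-r / lam)
    return VelocityField(vx=vx, vy=np.zeros_like(vx), grid_spacing=gs,
                         frame_interval=1.0), (cx, cy)


def test_plus_half_box_means_match_integration_oracle():
    """Box mean of the axial inflow template vs dense numerical integration."""
    v0, lam = 10.0, 500.0
    field, center = _plus_template(v0, lam)
    summary = plus_half_boxes(field, center)
    # independent fine-grid Riemann integration over the right box
    xs = np.linspace(25.0, 525.0, 800)
    ys = np.linspace(-375.0, 375.0, 1200)
    xg, yg = np.meshgrid(xs, ys)
    expected = (-v0 * np.exp(-np.hypot(xg, yg) / lam)).mean()
    assert summary.right.mean_vx == pytest.approx(expected, rel=0.05)
    assert summary.left.mean_vx == pytest.approx(-expected, rel=0.05)
    assert not summary.right.flagged


def test_plus_half_boxes_sign_pattern_and_zero_field():
    field, center = _plus_template()
    s = plus_half_boxes(field, center)
    assert s.right.mean_vx < 0 < s.left.mean_vx
    zero = VelocityField(vx=np.zeros((241, 241)), vy=np.zeros((241, 241)),
                         grid_spacing=10.0, frame_interval=1.0)
    sz = plus_half_boxes(zero, center)
    assert sz.right.mean_vx == sz.left.mean_vx == sz.top.mean_vy == sz.bottom.mean_vy == 0.0


def test_plus_half_boxes_are_disjoint_and_offset():
    field, center = _plus_template()
    s = plus_half_boxes(field, center)
    assert s.gap == 50.0 and s.box_w == 500.0 and s.box_h == 750.0


def _minus_scene(v0=10.0, lam=200.0):
    cfg = SceneConfig(shape=(4096, 4096), pixel_size=0.625, seed=5)
    xm, ym = cfg.extent
    field = ideal_director_field([PlantedDefect((xm / 2, ym / 2), -0.5, 0.0)], cfg,
                                 stride=64)
    rec = planted_record(field.meta["planted"][0], field)
    vel = defect_flow_field(rec, v0, lam, cfg, node_spacing=10.0)
    return vel, (xm / 2, ym / 2), rec.axes


def test_minus_half_sector_signs_and_radial_pattern():
    vel, center, legs = _minus_scene()
    s = minus_half_sectors(vel, center, legs)
    assert s.mean_vphi_A > 0 > s.mean_vphi_B
    assert s.mean_vr_off_leg > 0
    assert abs(s.mean_vr_on_leg) < 1e-9
    assert s.flags == ()


def test_minus_half_sector_means_match_integration_oracle():
    """Sector mean of the template's angular flow vs polar integration."""
    v0, lam = 10.0, 200.0
    vel, center, legs = _minus_scene(v0, lam)
    s = minus_half_sectors(vel, center, legs)
    r_hi = min(1800.0, center[0] - 10.0)
    rs = np.linspace(250.0, min(r_hi, np.hypot(center[0], center[1])), 400)
    # nodes live on a square grid: integrate only over radii fully inside
    rs = rs[rs <= center[0] - 20]
    deltas = np.linspace(-np.pi / 3, 0.0, 300)  # A-side of one leg
    rg, dg = np.meshgrid(rs, deltas)
    vphi = -v0 * np.exp(-rg / lam) * np.sin(3 * dg)
    keep = rg * np.abs(np.sin(dg)) > 45.0
    expected = (vphi * rg)[keep].sum() / rg[keep].sum()  # area-weighted polar mean
    # the grid average weights nodes uniformly; corners beyond r > extent are
    # clipped, so agreement is approximate but sign and scale must match
    assert s.mean_vphi_A == pytest.approx(expected, rel=0.25)


def test_minus_half_sectors_partition_annulus():
    vel, center, legs = _minus_scene()
    s = minus_half_sectors(vel, center, legs)
    xg, yg = vel.node_positions()
    r = np.hypot(xg - center[0], yg - center[1])
    in_annulus = ((r >= 250.0) & (r <= 1800.0) & vel.mask
                  & (r >= vel.grid_spacing / 2))
    assert s.n_A + s.n_B + s.n_on_leg == int(in_annulus.sum())
    assert s.n_off_leg == s.n_A + s.n_B


def test_minus_half_sectors_zero_field_and_validation():
    zero = VelocityField(vx=np.zeros((201, 201)), vy=np.zeros((201, 201)),
                         grid_spacing=10.0, frame_interval=1.0)
    s = minus_half_sectors(zero, (1000.0, 1000.0), (0.0, 2 * np.pi / 3, 4 * np.pi / 3),
                           r_min=100.0, r_max=900.0)
    assert s.mean_vphi_A == s.mean_vphi_B == 0.0
    with pytest.raises(ValueError):
        minus_half_sectors(zero, (1000.0, 1000.0), (0.0, 1.0))


def test_frame_rotation_invariance_of_box_summary():
    """Rotating the whole scene by 90 deg leaves the box summary unchanged."""
    v0, lam = 10.0, 500.0
    n, gs = 241, 10.0
    xg, yg = np.meshgrid(np.arange(n) * gs, np.arange(n) * gs)
    cx = cy = (n - 1) * gs / 2
    # same defect with tail along +y: rotate template and vectors by 90 deg
    r = np.hypot(xg - cx, yg - cy)
    v_axial = -v0 * np.sign(yg - cy) * np.exp(-r / lam)
    rotated = VelocityField(vx=np.zeros_like(v_axial), vy=v_axial,
                            grid_spacing=gs, frame_interval=1.0)
    base, center = _plus_template(v0, lam, n, gs)
    s0 = plus_half_boxes(base, center)
    s90 = plus_half_boxes(rotate_frame(rotated, center, np.pi / 2), center)
    assert s90.right.mean_vx == pytest.approx(s0.right.mean_vx, rel=0.05)
    assert s90.left.mean_vx == pytest.approx(s0.left.mean_vx, rel=0.05)


def test_control_summary_zero_and_drift_fields():
    zero = VelocityField(vx=np.zeros((241, 241)), vy=np.zeros((241, 241)),
                         grid_spacing=10.0, frame_interval=1.0)
    out = control_summary(zero, n_boxes=3, seed=1)
    assert all(s.right.mean_vx == 0.0 and s.left.mean_vx == 0.0 for s in out)
    drift = VelocityField(vx=np.full((241, 241), 1.5), vy=np.full((241, 241), -0.5),
                          grid_spacing=10.0, frame_interval=1.0)
    for s in control_summary(drift, n_boxes=3, seed=2):
        for box in (s.left, s.right, s.top, s.bottom):
            assert box.mean_vx == pytest.approx(1.5)
            assert box.mean_vy == pytest.approx(-0.5)


def test_control_summary_random_flow_centers_on_zero():
    from scipy import ndimage

    rng = np.random.default_rng(7)
    vx = ndimage.gaussian_filter(rng.standard_normal((241, 241)), 4.0)
    vy = ndimage.gaussian_filter(rng.standard_normal((241, 241)), 4.0)
    vx -= vx.mean()
    vy -= vy.mean()
    f = VelocityField(vx=vx, vy=vy, grid_spacing=10.0, frame_interval=1.0)
    means = [s.right.mean_vx for s in control_summary(f, n_boxes=21, seed=3)]
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(np.mean(means)) <= 3 * se + 1e-3


def test_control_summary_avoids_defects_or_raises():
    f = VelocityField(vx=np.zeros((241, 241)), vy=np.zeros((241, 241)),
                      grid_spacing=10.0, frame_interval=1.0)
    with pytest.raises(ValueError):
        control_summary(f, n_boxes=1, seed=0,
                        defect_positions=[(1200.0, 1200.0)], margin=5000.0)
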