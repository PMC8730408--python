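import numpy as np
import pytest

from mavessel.geometry import (BodyForceController, FlowDrive,
                               MAChannelGeometry, STUDY_BNRS,
                               build_ma_channel, pulsatile_modulation)


def csg_oracle(geom, pts):
    """Independent constructive-solid-geometry classification built from
    the primitive shapes (slab duct + truncated sphere)."""
    pts = np.asarray(pts)
    out = np.full(len(pts), -1)
    duct = (pts[:, 1] > 0) & (pts[:, 1] < geom.r2) \
        & (pts[:, 2] > 0) & (pts[:, 2] < geom.depth)
    c = geom.body_center
    sph = np.linalg.norm(pts - c, axis=1) < geom.body_radius
    body = sph & (pts[:, 1] >= geom.r2)
    out[duct] = 0
    out[body & ~duct] = 1
    return out


@pytest.mark.parametrize("bnr,r1", [(2.2, 11.0), (3.0, 15.0),
                                    (5.4, 27.0), (8.0, 40.0)])
def test_body_diameter_from_bnr_definition(bnr, r1):
    geom = build_ma_channel(bnr, r2=5.0)
    assert geom.R1 == pytest.approx(r1)
    assert geom.R1 / geom.r2 == pytest.approx(bnr)


def test_neck_wider_than_body_rejected():
    with pytest.raises(ValueError):
        MAChannelGeometry(bnr=1.5, neck_width=10.0)


def test_degenerate_hemispherical_pocket_watertight(rng):
    geom = build_ma_channel(1.0, r2=5.0, neck_width=5.0)
    pts = rng.uniform([-5, -10, -15], [geom.L + 5, 25, 25], (20000, 3))
    assert np.array_equal(geom.classify_points(pts), csg_oracle(geom, pts))


def test_centerline_and_body_center_classification():
    geom = build_ma_channel(5.4)
    assert geom.classify_point([geom.L / 2, geom.r2 / 2,
                                geom.depth / 2]) == "parent"
    assert geom.classify_point(geom.body_center) == "ma_body"
    assert geom.classify_point([0.0, -1.0, 5.0]) == "outside"


@pytest.mark.parametrize("bnr", STUDY_BNRS)
def test_classification_matches_csg_oracle(bnr, rng):
    geom = build_ma_channel(bnr)
    lo, hi = geom.bounding_box(pad=3.0)
    pts = rng.uniform(lo, hi, (100_000, 3))
    assert np.array_equal(geom.classify_points(pts), csg_oracle(geom, pts))


@pytest.mark.parametrize("bnr", [2.2, 5.4])
def test_lumen_volume_matches_monte_carlo(bnr, rng):
    geom = build_ma_channel(bnr)
    lo, hi = geom.bounding_box(pad=1.0)
    n = 600_000
    pts = rng.uniform(lo, hi, (n, 3))
    box_vol = np.prod(hi - lo)
    mc = (geom.classify_points(pts) >= 0).mean() * box_vol
    assert mc == pytest.approx(geom.lumen_volume, rel=0.01)


def test_wall_particles_outside_lumen_and_within_shell():
    geom = build_ma_channel(3.0)
    walls = geom.generate_wall_particles(1.0, 2.0)
    assert len(walls) > 100
    assert not geom.in_lumen(walls).any()


def test_wall_shell_thinner_than_cutoff_rejected():
    geom = build_ma_channel(3.0)
    with pytest.raises(ValueError):
        geom.generate_wall_particles(0.5, 2.0, fluid_cutoff=1.0)


# -- flow drive -------------------------------------------------------------

def test_pulsatile_reduces_to_static_at_zero_amplitude():
    d = FlowDrive(mode="pulsatile", amplitude_fraction=0.0, period_s=1.0)
    assert pulsatile_modulation(d, 0.37) == 1.0


def test_pulsatile_mean_is_one_over_integer_periods():
    d = FlowDrive(mode="pulsatile", amplitude_fraction=0.4, period_s=1.0)
    t = np.linspace(0, 3.0, 30_001)
    vals = [pulsatile_modulation(d, tk) for tk in t]
    assert np.trapezoid(vals, t) / 3.0 == pytest.approx(1.0, abs=1e-6)


def test_pulsatile_quarter_period_value():
    d = FlowDrive(mode="pulsatile", amplitude_fraction=0.4, period_s=1.0)
    assert pulsatile_modulation(d, 0.25) == pytest.approx(1.4)


def test_pulsatile_invalid_period_rejected():
    d = FlowDrive(mode="pulsatile", amplitude_fraction=0.4, period_s=1.0)
    with pytest.raises(ValueError):
        pulsatile_modulation(d, 1.0, period=0.0)


def test_controller_fixed_point_and_sign():
    c = BodyForceController(target_velocity=0.3, g0=0.1)
    g0 = c.g
    assert c.update(0.3) == pytest.approx(g0)      # measured = target
    c2 = BodyForceController(target_velocity=0.3, g0=0.1)
    assert c2.update(0.0) > 0.1                    # measured 0 -> increase
    c3 = BodyForceController(target_velocity=0.3, g0=0.1)
    assert c3.update(float("nan")) == 0.1          # hold on bad input
    assert c3.held == 1


def test_controller_converges_on_linear_plant():
    """Closed loop against v = chi * g reaches the target within 20% and
    then holds within 10%."""
    chi = 2.3
    c = BodyForceController(target_velocity=0.3, g0=0.05)
    vs = []
    for _ in range(40):
        v = chi * c.g
        vs.append(v)
        c.update(v)
    assert abs(vs[15] - 0.3) / 0.3 < 0.2
    assert all(abs(v - 0.3) / 0.3 < 0.1 for v in vs[-10:])
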