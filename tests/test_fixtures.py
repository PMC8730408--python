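import pytest

from mavessel.fixtures import (FixtureSpec, fixture_suite,
                               make_adhesion_doublet, make_mini_ma,
                               make_poiseuille_slab, make_rbc_stretch,
                               make_thermal_box)


def test_thermal_box_is_solvent_only_and_undriven():
    cfg = make_thermal_box(0)
    assert cfg.hematocrit == 0.0
    assert cfg.platelet_rate_per_s == 0.0


def test_poiseuille_slab_has_parent_cross_section():
    cfg = make_poiseuille_slab(1.5, 0)
    assert (cfg.r2, cfg.depth) == (5.0, 10.0)
    assert cfg.drive.target_mm_per_s == 1.5


def test_stretch_fixture_orders_presets():
    normal = make_rbc_stretch(0)
    diabetic = make_rbc_stretch(0, diabetic=True)
    assert normal["preset"] == "rbc_normal"
    assert diabetic["preset"] == "rbc_diabetic"
    assert normal["loads_model"][0] == 0.0


def test_doublet_flag_controls_adhesion():
    on = make_adhesion_doublet(True, 0)
    off = make_adhesion_doublet(False, 0)
    assert on.morse.enabled and not off.morse.enabled
    # quiescent: negligible drive
    assert on.drive.target_mm_per_s < 1e-3


@pytest.mark.parametrize("bnr", [2.2, 3.0, 5.4, 8.0])
def test_mini_ma_preserves_geometry_ratios(bnr):
    cfg = make_mini_ma(bnr, 0.20, 1.5, seed=0)
    geom = cfg.geometry
    assert geom.R1 / geom.r2 == pytest.approx(bnr)
    assert cfg.dpd.density < 3.0  # reduced solvent, true geometry


def test_mini_ma_rejects_off_study_conditions():
    with pytest.raises(ValueError):
        make_mini_ma(4.0, 0.2, 1.5)
    with pytest.raises(ValueError):
        make_mini_ma(3.0, 0.33, 1.5)


def test_mini_ma_smallest_body_diameter():
    cfg = make_mini_ma(2.2, 0.10, 1.5)
    assert cfg.geometry.R1 == pytest.approx(11.0)


def test_suite_lists_fixture_manifests():
    specs = fixture_suite(fast=True)
    assert all(isinstance(s, FixtureSpec) and s.checks for s in specs)
    names = {s.name for s in specs}
    assert {"thermal-box", "poiseuille"} <= names


def test_same_seed_same_config_content():
    a = make_mini_ma(3.0, 0.20, 1.5, seed=5)
    b = make_mini_ma(3.0, 0.20, 1.5, seed=5)
    assert (a.label, a.seed, a.n_steps, a.hematocrit, a.bnr) \
        == (b.label, b.seed, b.n_steps, b.hematocrit, b.bnr)
    assert (a.dpd.a == b.dpd.a).all()
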