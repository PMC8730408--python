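import numpy as np
import pytest

from mavessel.membrane import (CellModelParams, MembraneForceField,
                               WLCDivergenceError,
                               calibrate_wlc_to_shear_modulus, rbc_diabetic,
                               rbc_normal, platelet,
                               shear_modulus_from_network, total_free_energy,
                               wlc_tension)
from mavessel.meshes import ShapeSpec, build_cell_mesh


@pytest.fixture(scope="module")
def small_ff():
    spec = ShapeSpec("sphere", diameter=2.0)
    mesh = build_cell_mesh(spec, 42)
    params = CellModelParams(n_vertices=42, shape=spec,
                             A0tot=mesh.A0tot, V0tot=mesh.V0tot)
    return MembraneForceField(mesh, params)


def _fd_gradient(fun, x, h=1e-6):
    num = np.zeros_like(x)
    for i in range(x.shape[0]):
        for ax in range(3):
            xp = x.copy(); xp[i, ax] += h
            xm = x.copy(); xm[i, ax] -= h
            num[i, ax] = -(fun(xp)[0] - fun(xm)[0]) / (2 * h)
    return num


@pytest.mark.parametrize("term", ["elastic", "bending", "area_volume"])
def test_forces_are_exact_negative_gradients(small_ff, rng, term):
    """Central finite differences of each energy term agree with the
    analytic forces to < 1e-4 relative error on a perturbed mesh."""
    fun = getattr(small_ff, term)
    x = small_ff.mesh.x + 0.03 * rng.standard_normal(small_ff.mesh.x.shape)
    _, f = fun(x)
    num = _fd_gradient(fun, x)
    scale = max(np.abs(f).max(), 1e-12)
    assert np.abs(num - f).max() / scale < 1e-4


def test_reference_state_is_force_free_and_zero_constraint_energy(small_ff):
    energies, f = small_ff.total()
    assert energies["bending"] == pytest.approx(0.0, abs=1e-9)
    assert energies["area_volume"] == pytest.approx(0.0, abs=1e-9)
    assert np.abs(f).max() < 1e-8  # WLC attraction balances POW repulsion


def test_total_is_sum_of_terms(small_ff, rng):
    x = small_ff.mesh.x + 0.02 * rng.standard_normal(small_ff.mesh.x.shape)
    es, _ = small_ff.elastic(x)
    eb, _ = small_ff.bending(x)
    ea, _ = small_ff.area_volume(x)
    et, _ = small_ff.total(x)
    assert et["total"] == pytest.approx(es + eb + ea, rel=1e-12)


def test_energy_decreases_under_damped_relaxation(small_ff, rng):
    x = small_ff.mesh.x + 0.05 * rng.standard_normal(small_ff.mesh.x.shape)
    energies = []
    for _ in range(60):
        e, f = small_ff.total(x)
        energies.append(e["total"])
        x = x + 2e-5 * f  # gradient descent
    assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))


def test_wlc_tension_monotone_and_divergent():
    lm, p = 2.0, 0.01
    ls = np.linspace(0.2, 1.9, 40)
    t = [wlc_tension(l, lm, p) for l in ls]
    assert all(b > a for a, b in zip(t, t[1:]))
    # divergence approaching the maximum extension
    assert wlc_tension(0.999 * lm, lm, p) > 100 * wlc_tension(0.9 * lm,
                                                              lm, p)


def test_overstretched_edge_raises(small_ff):
    x = small_ff.mesh.x.copy()
    i, j = small_ff.mesh.edges[0]
    d = x[i] - x[j]
    x[i] = x[j] + d / np.linalg.norm(d) * small_ff.lm[0] * 1.01
    with pytest.raises(WLCDivergenceError):
        small_ff.elastic(x)


def test_inflated_sphere_volume_force_points_inward(small_ff):
    x = small_ff.mesh.x * 1.1  # V > V0
    _, f = small_ff.area_volume(x)
    outward = x - x.mean(axis=0)
    radial = np.einsum("ij,ij->i", f, outward)
    assert np.mean(radial < 0) > 0.95


def test_calibration_round_trip_hits_target():
    cal = calibrate_wlc_to_shear_modulus(1104.0, x0=1 / 2.2, l0=0.6)
    mu = shear_modulus_from_network(cal["p"], cal["k_p"], 0.6, 1 / 2.2)
    assert mu == pytest.approx(1104.0, rel=1e-10)


def test_calibration_scales_linearly_with_target_and_kbt():
    base = calibrate_wlc_to_shear_modulus(100.0, x0=0.45, l0=0.5)
    five = calibrate_wlc_to_shear_modulus(500.0, x0=0.45, l0=0.5)
    assert five["p"] == pytest.approx(base["p"] / 5.0)
    # doubling kBT at fixed p doubles both network contributions
    mu1 = shear_modulus_from_network(base["p"],
                                     base["k_p"], 0.5, 0.45, kBT=1.0)
    cal2_kp = base["k_p"] * 2.0  # balance condition is linear in kBT
    mu2 = shear_modulus_from_network(base["p"], cal2_kp, 0.5, 0.45, kBT=2.0)
    assert mu2 == pytest.approx(2.0 * mu1)


def test_presets_encode_study_ratios():
    n, d, p = rbc_normal(), rbc_diabetic(), platelet()
    assert d.shear_modulus_uN_per_m / n.shear_modulus_uN_per_m \
        == pytest.approx(5.0)
    assert p.shear_modulus_uN_per_m / n.shear_modulus_uN_per_m \
        == pytest.approx(100.0)
    assert p.bending_rigidity_J / n.bending_rigidity_J \
        == pytest.approx(100.0)
    assert n.n_vertices == 500 and p.n_vertices == 48
    assert n.A0tot == pytest.approx(132.9) and n.V0tot == pytest.approx(92.5)
    assert p.V0tot == pytest.approx(6.0)


def test_invalid_x0_rejected():
    with pytest.raises(ValueError):
        calibrate_wlc_to_shear_modulus(10.0, x0=1.2, l0=0.5)


def test_free_energy_breakdown_reported(rbc_coarse):
    mesh, params = rbc_coarse
    e = total_free_energy(mesh, params)
    assert set(e) == {"elastic", "bending", "area_volume", "total"}
    assert e["total"] == pytest.approx(
        e["elastic"] + e["bending"] + e["area_volume"])
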