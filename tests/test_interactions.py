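import numpy as np
import pytest
from hypothesis import given, strategies as st

from mavessel.dpd import Box, ParticleSystem, RBC
from mavessel.interactions import (InteractionMatrix, MorseParams,
                                   UnknownCellError, intercell_pair_forces,
                                   morse_force, morse_potential)
from mavessel.meshes import ShapeSpec, build_cell_mesh


@pytest.fixture()
def morse():
    return MorseParams()


def test_minimum_at_zero_force_distance(morse):
    assert morse_potential(morse.r0, morse, shifted=False) \
        == pytest.approx(-morse.De)


def test_decay_negligible_near_cutoff(morse):
    v = morse_potential(0.995 * morse.r_cut, morse, shifted=False)
    assert -1.1e-3 * morse.De < v < 0.0
    assert morse.tail_magnitude() < 1e-3


def test_value_at_ln2_over_beta(morse):
    """At r = r0 + ln(2)/beta the exponential halves:
    V = De*(1/4 - 2*1/2) = -0.75*De."""
    r = morse.r0 + np.log(2.0) / morse.beta
    assert morse_potential(r, morse, shifted=False) \
        == pytest.approx(-0.75 * morse.De)


def test_cutoff_tail_negligible(morse):
    assert morse.tail_magnitude() < 1e-3


def test_nonpositive_separation_rejected(morse):
    with pytest.raises(ValueError):
        morse_potential(0.0, morse)
    with pytest.raises(ValueError):
        morse_force([0.0, 0.0, 0.0], morse)


def test_force_zero_at_r0_repulsive_inside_attractive_outside(morse):
    assert np.allclose(morse_force([morse.r0, 0, 0], morse), 0.0,
                       atol=1e-12)
    f_in = morse_force([0.9 * morse.r0, 0, 0], morse)
    assert f_in[0] > 0  # pushes apart
    f_out = morse_force([1.3 * morse.r0, 0, 0], morse)
    assert f_out[0] < 0  # pulls together
    assert np.all(morse_force([morse.r_cut * 1.01, 0, 0], morse) == 0.0)


@given(st.floats(0.15, 1.7))
def test_force_is_negative_gradient_of_potential(r):
    p = MorseParams()
    h = 1e-7
    if not (p.r0 * 0.3 < r < p.r_cut * 0.98):
        return
    num = -(morse_potential(r + h, p) - morse_potential(r - h, p)) / (2 * h)
    ana = morse_force([r, 0, 0], p)[0]
    assert ana == pytest.approx(num, rel=1e-5, abs=1e-8)


# -- intercellular force assembly ------------------------------------------

def _two_cell_system(gap, n=42, enabled=True):
    mesh = build_cell_mesh(ShapeSpec("sphere", diameter=2.0), n)
    x1 = mesh.x.copy()
    x2 = mesh.x + np.array([2.0 + gap, 0.0, 0.0])
    x = np.vstack([x1, x2]) + 10.0
    ptype = np.full(2 * n, RBC, dtype=np.int64)
    cid = np.concatenate([np.zeros(n), np.ones(n)]).astype(np.int64)
    sys_ = ParticleSystem(x, np.zeros_like(x), ptype, cid,
                          Box.cube(40.0, periodic=False))
    return sys_, InteractionMatrix(morse=MorseParams(enabled=enabled))


def test_distant_cells_no_intercell_force():
    sys_, mat = _two_cell_system(gap=3.0)
    f = intercell_pair_forces(sys_, mat)
    assert np.abs(f).max() == 0.0


def test_adhesion_off_equals_repulsion_only():
    sys_on, mat_on = _two_cell_system(gap=0.6, enabled=True)
    sys_off, mat_off = _two_cell_system(gap=0.6, enabled=False)
    f_on = intercell_pair_forces(sys_on, mat_on)
    f_off = intercell_pair_forces(sys_off, mat_off)
    # with adhesion the near-contact pair attracts more (or repels less)
    n = len(f_on) // 2
    assert f_on[:n, 0].sum() > f_off[:n, 0].sum()
    # off-path forces contain no Morse attraction: conservative DPD only
    assert np.isfinite(f_off).all()


def test_near_contact_cells_attract_with_adhesion():
    # gap inside the Morse attraction zone but beyond the DPD core
    sys_, mat = _two_cell_system(gap=1.05, enabled=True)
    f = intercell_pair_forces(sys_, mat)
    n = len(f) // 2
    # net force on cell 1 points toward cell 2 (+x)
    assert f[:n, 0].sum() > 0.0
    # Newton's third law across the cells
    assert np.allclose(f[:n].sum(axis=0), -f[n:].sum(axis=0), atol=1e-9)


def test_unknown_cell_id_rejected():
    sys_, mat = _two_cell_system(gap=0.5)
    with pytest.raises(UnknownCellError):
        intercell_pair_forces(sys_, mat, n_cells=1)


def test_interaction_matrix_kinds():
    mat = InteractionMatrix()
    from mavessel.dpd import PLATELET, SOLVENT, WALL
    assert mat.kind(WALL, WALL) == "none"
    assert mat.kind(RBC, RBC) == "morse+dpd"
    assert mat.kind(RBC, PLATELET) == "dpd"
    assert mat.kind(SOLVENT, RBC) == "dpd"
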