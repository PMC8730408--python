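import numpy as np
import pytest

from mavessel.dpd import (Box, CoincidentParticlesError, DPDParams,
                          ParticleSystem, SOLVENT, WALL,
                          build_neighbor_list, integrate_step,
                          measure_temperature, pairwise_dpd_force)


@pytest.fixture()
def params():
    return DPDParams()


def solvent_system(x, L=10.0, periodic=True):
    n = len(x)
    return ParticleSystem(x, np.zeros((n, 3)),
                          np.zeros(n, dtype=np.int64),
                          np.full(n, -1, dtype=np.int64),
                          Box.cube(L, periodic))


# -- pairwise forces --------------------------------------------------------

def test_force_zero_beyond_cutoff(params):
    f = pairwise_dpd_force([0, 0, 0], [1.01 * params.r_c, 0, 0],
                           [0, 0, 0], [0, 0, 0], 0, 0, params, noise=0.7)
    assert np.all(f == 0.0)


def test_newtons_third_law_with_shared_noise(params, rng):
    xi, xj = rng.uniform(0, 0.8, 3), rng.uniform(0, 0.8, 3)
    vi, vj = rng.standard_normal(3), rng.standard_normal(3)
    fij = pairwise_dpd_force(xi, xj, vi, vj, 0, 0, params, noise=0.31)
    fji = pairwise_dpd_force(xj, xi, vj, vi, 0, 0, params, noise=0.31)
    assert np.allclose(fij + fji, 0.0, atol=1e-15)


def test_conservative_only_magnitude_matches_closed_form(params):
    """Head-on pair with gamma = sigma = 0 at r = r_c/2: |F| = a*(1 - r/rc)
    (the conservative weight)."""
    p = DPDParams(gamma=np.zeros((4, 4)), sigma=np.zeros((4, 4)))
    r = p.r_c / 2
    f = pairwise_dpd_force([0, 0, 0], [r, 0, 0], [0, 0, 0], [0, 0, 0],
                           0, 0, p, noise=0.9)
    assert np.linalg.norm(f) == pytest.approx(p.a[0, 0] * (1 - r / p.r_c))
    assert f[0] < 0  # pushes i away from j (j at +x)


def test_force_is_central(params, rng):
    xi, xj = rng.uniform(0, 0.8, 3), rng.uniform(0, 0.8, 3)
    f = pairwise_dpd_force(xi, xj, rng.standard_normal(3),
                           rng.standard_normal(3), 0, 0, params, noise=0.2)
    r = np.asarray(xi) - np.asarray(xj)
    cross = np.cross(f, r)
    assert np.linalg.norm(cross) < 1e-12 * max(np.linalg.norm(f), 1.0)


def test_coincident_particles_rejected(params):
    with pytest.raises(CoincidentParticlesError):
        pairwise_dpd_force([1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0],
                           0, 0, params, noise=0.0)


def test_fluctuation_dissipation_constraint(params):
    assert params.fluctuation_dissipation_ok()
    bad = DPDParams(sigma=np.full((4, 4), 1.0))
    assert not bad.fluctuation_dissipation_ok()


# -- integrator -------------------------------------------------------------

def test_zero_forces_zero_velocity_leaves_positions(rng):
    sys_ = solvent_system(rng.uniform(0, 10, (20, 3)))
    x0 = sys_.x.copy()
    integrate_step(sys_, np.zeros((20, 3)), dt=0.01)
    assert np.allclose(sys_.x, x0)


def test_constant_force_matches_leapfrog_closed_form():
    """Free unit-mass particle under constant force f: the kick-drift
    recursion gives x_n = x0 + dt^2 * f * n(n+1)/2 and v_n = n*dt*f."""
    sys_ = solvent_system(np.array([[5.0, 5.0, 5.0]]), L=1e6)
    f = np.array([[0.3, -0.1, 0.2]])
    dt, n = 0.01, 200
    for _ in range(n):
        integrate_step(sys_, f, dt)
    expected = 5.0 + dt**2 * f[0] * n * (n + 1) / 2
    assert np.allclose(sys_.x[0], expected, atol=1e-10)
    assert np.allclose(sys_.v[0], n * dt * f[0], atol=1e-12)


def test_wall_particles_never_move(rng):
    x = rng.uniform(0, 10, (10, 3))
    sys_ = solvent_system(x)
    sys_.ptype[:5] = WALL
    x0 = sys_.x.copy()
    integrate_step(sys_, rng.standard_normal((10, 3)), dt=0.05)
    assert np.allclose(sys_.x[:5], x0[:5])
    assert not np.allclose(sys_.x[5:], x0[5:])


def test_nan_force_aborts_with_particle_index(rng):
    sys_ = solvent_system(rng.uniform(0, 10, (5, 3)))
    f = np.zeros((5, 3))
    f[3, 1] = np.nan
    with pytest.raises(FloatingPointError, match="particle 3"):
        integrate_step(sys_, f, dt=0.01)


def test_pair_energy_conservation_conservative_only():
    """An isolated conservative-only pair drifts < 1e-4 in relative energy
    over 1e4 velocity-Verlet steps at small dt."""
    p = DPDParams(gamma=np.zeros((4, 4)), sigma=np.zeros((4, 4)))
    a, rc = p.a[0, 0], p.r_c

    def pot(r):
        return 0.5 * a * rc * (1 - r / rc) ** 2 if r < rc else 0.0

    sys_ = solvent_system(np.array([[5.0, 5, 5], [5.6, 5, 5]]), L=20.0)
    sys_.v[0] = [0.05, 0, 0]
    dt = 1e-3
    e0 = None
    for step in range(10_000):
        r_vec = sys_.x[0] - sys_.x[1]
        r = np.linalg.norm(r_vec)
        f0 = pairwise_dpd_force(sys_.x[0], sys_.x[1], sys_.v[0], sys_.v[1],
                                0, 0, p, noise=0.0) if r < rc \
            else np.zeros(3)
        if step > 0:
            # synchronize the half-step leapfrog velocities with positions
            v_sync = sys_.v + 0.5 * dt * np.array([f0, -f0])
            e = pot(r) + 0.5 * (v_sync**2).sum()
            if e0 is None:
                e0 = e
        integrate_step(sys_, np.array([f0, -f0]), dt)
    assert abs(e - e0) / e0 < 1e-4


# -- neighbor search --------------------------------------------------------

def test_two_far_particles_no_pairs():
    sys_ = solvent_system(np.array([[1.0, 1, 1], [8.0, 8, 8]]))
    assert len(build_neighbor_list(sys_, 1.0)) == 0


def test_minimum_image_across_seam():
    L = 10.0
    sys_ = solvent_system(np.array([[0.1, 5, 5], [L - 0.1, 5, 5]]))
    pairs = build_neighbor_list(sys_, 0.5)
    assert pairs.tolist() == [[0, 1]]


def test_cutoff_beyond_half_box_rejected(rng):
    sys_ = solvent_system(rng.uniform(0, 10, (10, 3)))
    with pytest.raises(ValueError):
        build_neighbor_list(sys_, 5.5)


@pytest.mark.parametrize("seed", range(20))
def test_neighbor_list_matches_all_pairs_oracle(seed):
    """Cell-list pairs equal a brute-force O(N^2) minimum-image scan,
    including pairs straddling the periodic seam."""
    rng = np.random.default_rng(seed)
    L, cutoff = 6.0, 1.1
    n = 200
    x = rng.uniform(0, L, (n, 3))
    sys_ = solvent_system(x, L=L)
    pairs = {tuple(p) for p in build_neighbor_list(sys_, cutoff).tolist()}
    d = x[:, None, :] - x[None, :, :]
    d -= np.round(d / L) * L
    dist2 = (d**2).sum(-1)
    iu, ju = np.triu_indices(n, 1)
    brute = {(int(i), int(j)) for i, j in zip(iu, ju)
             if dist2[i, j] < cutoff**2}
    assert pairs == brute


# -- thermometry ------------------------------------------------------------

def test_zero_velocities_zero_temperature():
    assert measure_temperature(np.zeros((50, 3))) == 0.0


def test_maxwell_boltzmann_sample_recovers_kbt(rng):
    v = rng.normal(0, 1.0, (200_000, 3))
    assert measure_temperature(v) == pytest.approx(1.0, rel=0.01)


def test_empty_window_rejected():
    with pytest.raises(ValueError):
        measure_temperature(np.zeros((0, 3)))


def test_wall_particles_excluded_from_temperature():
    v = np.ones((10, 3))
    ptype = np.zeros(10, dtype=int)
    ptype[:5] = WALL
    v[:5] = 100.0
    assert measure_temperature(v, ptype) == pytest.approx(1.0)
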