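"""Dissipative particle dynamics: parameters, particle containers and the
core operations (pair forces, integration, neighbor search, thermometry).

The force on particle i from particle j within the cutoff r_c is the
standard conservative/dissipative/random triplet

    F_ij = a_ij (1 - r/r_c) e_ij
         - gamma w_R(r)^2 (e_ij . v_ij) e_ij
         + sigma w_R(r) theta_ij / sqrt(dt) e_ij

with w_R(r) = (1 - r/r_c)^s and the fluctuation-dissipation constraint
sigma^2 = 2 gamma kBT for every type pair.  ``s`` defaults to 0.25, a common
soft-matter choice that raises the fluid viscosity relative to s = 1.

Particle types: 0 = solvent, 1 = wall (frozen), 2 = RBC membrane vertex,
3 = platelet membrane vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from . import _kernels

SOLVENT, WALL, RBC, PLATELET = 0, 1, 2, 3
TYPE_NAMES = {SOLVENT: "solvent", WALL: "wall", RBC: "rbc_membrane",
              PLATELET: "platelet_membrane"}
N_TYPES = 4


class CoincidentParticlesError(ValueError):
    """Two particles sit at the same position (degenerate pair direction)."""


def _default_a() -> np.ndarray:
    a = np.full((N_TYPES, N_TYPES), 25.0)
    for t in (RBC, PLATELET):
        a[SOLVENT, t] = a[t, SOLVENT] = 25.0   # solvent-membrane cushion
    a[RBC, RBC] = 25.0                         # soft RBC-RBC core so the
    a[RBC, PLATELET] = a[PLATELET, RBC] = 50.0  # Morse well can win outside
    a[PLATELET, PLATELET] = 50.0               # it; stiffer for platelets
    a[WALL, WALL] = 0.0
    return a


def _default_gamma() -> np.ndarray:
    g = np.full((N_TYPES, N_TYPES), 4.5)
    for t in (RBC, PLATELET):
        g[SOLVENT, t] = g[t, SOLVENT] = 20.0   # no-slip membrane coupling
    g[SOLVENT, WALL] = g[WALL, SOLVENT] = 15.0  # no-slip wall friction
    g[WALL, WALL] = 0.0
    return g


@dataclass
class DPDParams:
    """DPD coefficients per type pair plus global constants.

    ``sigma`` is derived from ``gamma`` and ``kBT`` through the
    fluctuation-dissipation relation; supplying it explicitly is only useful
    to construct deliberately inconsistent parameter sets in tests.
    """

    a: np.ndarray = field(default_factory=_default_a)
    gamma: np.ndarray = field(default_factory=_default_gamma)
    r_c: float = 1.0
    s: float = 0.25
    kBT: float = 1.0
    density: float = 3.0  # solvent number density (per cubic model length)
    dt: float = 0.01
    gamma_intra: float = 15.0  # same-membrane bonded-pair thermostat
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        if self.a.shape != (N_TYPES, N_TYPES) \
                or self.gamma.shape != (N_TYPES, N_TYPES):
            raise ValueError("a and gamma must be 4x4 type-pair matrices")
        if not (np.allclose(self.a, self.a.T)
                and np.allclose(self.gamma, self.gamma.T)):
            raise ValueError("type-pair matrices must be symmetric")
        if self.r_c <= 0 or self.kBT <= 0 or self.dt <= 0:
            raise ValueError("r_c, kBT and dt must be positive")
        if np.any(self.a < 0) or np.any(self.gamma < 0):
            raise ValueError("DPD coefficients must be non-negative")
        self.sigma_intra = math.sqrt(2.0 * self.gamma_intra * self.kBT)
        if self.sigma is None:
            self.sigma = np.sqrt(2.0 * self.gamma * self.kBT)
        else:
            self.sigma = np.asarray(self.sigma, dtype=np.float64)

    def fluctuation_dissipation_ok(self, rtol: float = 1e-10) -> bool:
        return np.allclose(self.sigma**2, 2.0 * self.gamma * self.kBT,
                           rtol=rtol)


@dataclass
class Box:
    """Axis-aligned domain with per-axis periodicity."""

    lo: np.ndarray
    hi: np.ndarray
    periodic: np.ndarray  # (3,) bool

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=np.float64)
        self.hi = np.asarray(self.hi, dtype=np.float64)
        self.periodic = np.asarray(self.periodic, dtype=np.bool_)
        if np.any(self.hi <= self.lo):
            raise ValueError("box extents must be positive")

    @property
    def span(self) -> np.ndarray:
        return self.hi - self.lo

    @classmethod
    def cube(cls, L: float, periodic: bool = True) -> "Box":
        return cls(np.zeros(3), np.full(3, float(L)), np.full(3, periodic))


@dataclass
class ParticleSystem:
    """Positions, velocities, types and membrane ownership of all particles."""

    x: np.ndarray                     # (N, 3)
    v: np.ndarray                     # (N, 3)
    ptype: np.ndarray                 # (N,) int64
    cell_id: np.ndarray               # (N,) int64, -1 for none
    box: Box
    mass: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.ascontiguousarray(self.x, dtype=np.float64)
        self.v = np.ascontiguousarray(self.v, dtype=np.float64)
        self.ptype = np.ascontiguousarray(self.ptype, dtype=np.int64)
        self.cell_id = np.ascontiguousarray(self.cell_id, dtype=np.int64)
        n = len(self.x)
        if not (len(self.v) == len(self.ptype) == len(self.cell_id) == n):
            raise ValueError("array lengths disagree")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def mobile(self) -> np.ndarray:
        return self.ptype != WALL

    def validate(self) -> None:
        if not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite coordinates")
        if np.any(np.abs(self.v[self.ptype == WALL]) > 0):
            raise ValueError("wall particles must have zero velocity")
        for ax in range(3):
            if self.box.periodic[ax]:
                inside = (self.x[:, ax] >= self.box.lo[ax]) \
                    & (self.x[:, ax] < self.box.hi[ax])
                if not np.all(inside):
                    raise ValueError(
                        f"coordinates outside the periodic axis {ax}")


# ---------------------------------------------------------------------------
# operations


def pairwise_dpd_force(xi, xj, vi, vj, ti, tj, params: DPDParams,
                       noise: float, dt: float | None = None) -> np.ndarray:
    """DPD force on particle i from particle j for an explicit noise draw.

    Central (parallel to r_ij), exactly antisymmetric under i<->j with the
    shared symmetric noise, zero beyond the cutoff.  Raises for coincident
    particles.
    """
    dt = params.dt if dt is None else dt
    r_vec = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise CoincidentParticlesError("coincident particles: the pair "
                                       "direction is undefined")
    if r >= params.r_c:
        return np.zeros(3)
    e = r_vec / r
    wc = 1.0 - r / params.r_c
    wr = wc ** params.s
    v_rel = np.asarray(vi, dtype=float) - np.asarray(vj, dtype=float)
    fmag = params.a[ti, tj] * wc \
        - params.gamma[ti, tj] * wr * wr * float(e @ v_rel) \
        + params.sigma[ti, tj] * wr * noise / np.sqrt(dt)
    return fmag * e


def integrate_step(system: ParticleSystem, forces: np.ndarray,
                   dt: float) -> ParticleSystem:
    """One kick-drift leapfrog step: v += dt*F(x); x += dt*v.

    Symplectic when the caller evaluates forces at the current positions
    before each call (velocities are then defined at half steps).  Wall
    particles never move; x is wrapped along periodic axes.  The full DPD
    loop in the simulation driver uses the two-half-kick form so the
    velocity-dependent dissipative force is evaluated mid-step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    forces = np.asarray(forces, dtype=np.float64)
    if not np.all(np.isfinite(forces)):
        bad = int(np.flatnonzero(~np.isfinite(forces).all(axis=1))[0])
        raise FloatingPointError(f"non-finite force on particle {bad}")
    mob = system.mobile
    system.v[mob] += dt * forces[mob] / system.mass
    system.x[mob] += dt * system.v[mob]
    for ax in range(3):
        if system.box.periodic[ax]:
            span = system.box.span[ax]
            system.x[:, ax] = system.box.lo[ax] \
                + (system.x[:, ax] - system.box.lo[ax]) % span
    return system


def build_neighbor_list(system: ParticleSystem, cutoff: float) -> np.ndarray:
    """Unordered index pairs with minimum-image distance < cutoff."""
    for ax in range(3):
        if system.box.periodic[ax] and cutoff > 0.5 * system.box.span[ax]:
            raise ValueError("cutoff exceeds half the box along a periodic "
                             "axis: minimum image is ambiguous")
    pairs = _kernels.neighbor_pairs(system.x, system.n, system.box.lo,
                                    system.box.hi, cutoff,
                                    system.box.periodic)
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def measure_temperature(velocities, ptype=None) -> float:
    """Mean kinetic energy per particle per degree of freedom (= kBT in
    equilibrium, unit mass).  ``velocities`` is one (N, 3) frame or an
    iterable of frames; wall particles are excluded when ``ptype`` is given.
    """
    frames = np.asarray(velocities, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.size == 0 or frames.shape[1] == 0:
        raise ValueError("empty velocity window")
    if ptype is not None:
        frames = frames[:, np.asarray(ptype) != WALL, :]
        if frames.shape[1] == 0:
            raise ValueError("no mobile particles in the window")
    return float(np.mean(frames**2))


def total_momentum(system: ParticleSystem) -> np.ndarray:
    return system.v[system.mobile].sum(axis=0) * system.mass
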