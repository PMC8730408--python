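"""Triangulated-network membrane mechanics.

The free energy of a cell membrane is the sum of four terms::

    V_t = V_s + V_b + V_a + V_v

* ``V_s`` -- in-plane elasticity: each mesh edge carries an attractive
  worm-like-chain (WLC) spring plus a power-law repulsive spring, balanced so
  the built geometry is the stress-free state;
* ``V_b`` -- bending: ``k_b (1 - cos(theta - theta_0))`` on each pair of
  adjacent triangles;
* ``V_a`` -- surface-area constraint (global quadratic penalty plus an
  optional local per-triangle term);
* ``V_v`` -- volume constraint (global quadratic penalty).

The WLC/POW network parameters are calibrated to a target macroscopic shear
modulus through the closed-form small-strain relation for a hexagonal
WLC-plus-power-repulsion network (power exponent m = 2)::

    mu_0 = (sqrt(3) kT / (4 p l_m x0)) * ( x0/(2(1-x0)^3) - 1/(4(1-x0)^2) + 1/4 )
         + 3 sqrt(3) k_p / (4 l0^3)

and the bending coefficient maps from the continuum bending rigidity k0 via
the standard triangulated-sheet correspondence ``k_b = 2 k0 / sqrt(3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np

from . import _kernels
from .meshes import (ShapeSpec, TriangulatedMembrane, build_cell_mesh,
                     dihedral_angles, mesh_area_volume, triangle_areas)
from .units import DEFAULT_UNITS, UnitSystem

#: printed macroscopic parameters of the normal red blood cell
RBC_SHEAR_MODULUS_UN_PER_M = 4.73
RBC_BENDING_RIGIDITY_J = 2.4e-19
RBC_AREA_UM2 = 132.9
RBC_VOLUME_UM3 = 92.5
RBC_N_VERTICES = 500
#: platelet: near-rigid oblate spheroid
PLATELET_N_VERTICES = 48
PLATELET_ASPECT_RATIO = 0.38
PLATELET_VOLUME_UM3 = 6.0
PLATELET_STIFFNESS_FACTOR = 100.0
#: diabetic preset stiffening factor
DIABETIC_STIFFNESS_FACTOR = 5.0


class WLCDivergenceError(ValueError):
    """An edge reached its maximum WLC extension."""


class DegenerateTriangleError(ValueError):
    """A mesh triangle has (numerically) zero area."""


@dataclass(frozen=True)
class CellModelParams:
    """Macroscopic membrane parameters plus penalty coefficients.

    Moduli are given in physical units (uN/m, J) and converted internally
    through ``units``; penalty coefficients are in model units.  ``x0`` is
    the ratio of the rest length to the maximum WLC extension.
    """

    n_vertices: int = RBC_N_VERTICES
    shear_modulus_uN_per_m: float = RBC_SHEAR_MODULUS_UN_PER_M
    bending_rigidity_J: float = RBC_BENDING_RIGIDITY_J
    A0tot: float = RBC_AREA_UM2       # um^2
    V0tot: float = RBC_VOLUME_UM3     # um^3
    shape: ShapeSpec | None = None
    k_a: float = 4900.0    # global-area penalty coefficient
    k_v: float = 4900.0    # volume penalty coefficient
    k_d: float = 100.0     # local-area penalty coefficient
    x0: float = 1.0 / 2.2  # rest length over maximum extension
    kBT: float = 1.0       # model energy units
    units: UnitSystem = DEFAULT_UNITS

    def __post_init__(self) -> None:
        if not (0.0 < self.x0 < 1.0):
            raise ValueError("x0 must lie strictly between 0 and 1")
        if min(self.shear_modulus_uN_per_m, self.bending_rigidity_J,
               self.A0tot, self.V0tot) <= 0:
            raise ValueError("moduli and reference area/volume must be positive")

    @property
    def mu0_model(self) -> float:
        return self.units.to_model_shear_modulus(self.shear_modulus_uN_per_m)

    @property
    def kb_model(self) -> float:
        """Dihedral bending coefficient, k_b = 2 k0 / sqrt(3)."""
        return 2.0 * self.units.to_model_energy(self.bending_rigidity_J) \
            / math.sqrt(3.0)

    @property
    def shape_spec(self) -> ShapeSpec:
        if self.shape is not None:
            return self.shape
        return ShapeSpec("biconcave", area=self.A0tot)


def rbc_normal(**overrides) -> CellModelParams:
    return replace(CellModelParams(), **overrides) if overrides \
        else CellModelParams()


def rbc_diabetic(**overrides) -> CellModelParams:
    p = CellModelParams(
        shear_modulus_uN_per_m=DIABETIC_STIFFNESS_FACTOR
        * RBC_SHEAR_MODULUS_UN_PER_M)
    return replace(p, **overrides) if overrides else p


def platelet(**overrides) -> CellModelParams:
    spec = ShapeSpec("oblate", aspect_ratio=PLATELET_ASPECT_RATIO,
                     volume=PLATELET_VOLUME_UM3)
    area = None
    p = CellModelParams(
        n_vertices=PLATELET_N_VERTICES,
        shear_modulus_uN_per_m=PLATELET_STIFFNESS_FACTOR
        * RBC_SHEAR_MODULUS_UN_PER_M,
        bending_rigidity_J=PLATELET_STIFFNESS_FACTOR * RBC_BENDING_RIGIDITY_J,
        A0tot=1.0,  # replaced below from the analytic shape
        V0tot=PLATELET_VOLUME_UM3,
        shape=spec,
    )
    from .meshes import analytic_area_volume
    area, _ = analytic_area_volume(spec)
    p = replace(p, A0tot=area)
    return replace(p, **overrides) if overrides else p


PRESETS = {"rbc_normal": rbc_normal, "rbc_diabetic": rbc_diabetic,
           "platelet": platelet}


def build_preset_mesh(name: str, n_vertices: int | None = None,
                      seed: int = 0) -> tuple[TriangulatedMembrane,
                                              CellModelParams]:
    """Build the mesh and parameter set of a named cell preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; valid: {sorted(PRESETS)}")
    params = PRESETS[name]()
    if n_vertices is not None:
        params = replace(params, n_vertices=n_vertices)
    mesh = build_cell_mesh(params.shape_spec, params.n_vertices, seed=seed)
    return mesh, params


# ---------------------------------------------------------------------------
# WLC network calibration


def wlc_tension(l: float, lm: float, p: float, kBT: float = 1.0) -> float:
    """WLC restoring tension at extension l (diverges as l -> lm)."""
    x = l / lm
    return (kBT / p) * (0.25 / (1 - x) ** 2 - 0.25 + x)


def shear_modulus_from_network(p: float, k_p: float, l0: float, x0: float,
                               kBT: float = 1.0) -> float:
    """Closed-form small-strain shear modulus of the WLC + POW (m = 2)
    hexagonal network."""
    lm = l0 / x0
    wlc = (math.sqrt(3.0) * kBT / (4.0 * p * lm * x0)) * (
        x0 / (2.0 * (1 - x0) ** 3) - 0.25 / (1 - x0) ** 2 + 0.25)
    pow_term = 3.0 * math.sqrt(3.0) * k_p / (4.0 * l0 ** 3)
    return wlc + pow_term


def calibrate_wlc_to_shear_modulus(target_mu0: float, x0: float, l0: float,
                                   kBT: float = 1.0) -> dict:
    """Solve for the persistence length p (and the repulsion coefficient k_p
    balancing each edge at its rest length) that reproduce ``target_mu0``
    through the closed-form network relation.

    Both the WLC and the balancing POW contribution scale as 1/p, so the
    calibration is a single division.  Returns a dict with keys
    ``p, k_p, lm``.
    """
    if target_mu0 <= 0:
        raise ValueError("target shear modulus must be positive")
    if not (0.0 < x0 < 1.0):
        raise ValueError("x0 must lie strictly between 0 and 1")
    mu_at_p1 = shear_modulus_from_network(1.0, _kp_balance(1.0, x0, l0, kBT),
                                          l0, x0, kBT)
    p = mu_at_p1 / target_mu0
    return {"p": p, "k_p": _kp_balance(p, x0, l0, kBT), "lm": l0 / x0}


def _kp_balance(p: float, x0: float, l0: float, kBT: float) -> float:
    """POW coefficient balancing the WLC tension at the rest length
    (exponent m = 2: f_pow = k_p / l^2)."""
    return wlc_tension(l0, l0 / x0, p, kBT) * l0 ** 2


# ---------------------------------------------------------------------------
# per-mesh packed force field


class MembraneForceField:
    """Packed per-edge/per-triangle coefficient arrays for one or more
    meshes, evaluated through the numba kernels."""

    def __init__(self, mesh: TriangulatedMembrane, params: CellModelParams):
        if mesh.l0 is None:
            mesh.set_reference()
        self.mesh = mesh
        self.params = params
        cal = calibrate_wlc_to_shear_modulus(params.mu0_model, params.x0,
                                             float(np.mean(mesh.l0)),
                                             params.kBT)
        self.p = cal["p"]
        # per-edge maximum extension and balancing repulsion from each
        # edge's own rest length (shape-specific stress-free state)
        self.lm = mesh.l0 / params.x0
        self.kp = np.array([_kp_balance(self.p, params.x0, l, params.kBT)
                            for l in mesh.l0])
        self.kbt_over_p = np.full(mesh.n_edges, params.kBT / self.p)
        self.kb = np.full(mesh.n_edges, params.kb_model)
        self.theta0 = mesh.theta0.copy()
        self.tri_cell = np.zeros(mesh.n_triangles, dtype=np.int64)

    # -- individual terms (energy, forces) ---------------------------------
    def elastic(self, x: np.ndarray | None = None):
        x = self.mesh.x if x is None else x
        f = np.zeros_like(x)
        e, worst = _kernels.wlc_pow_forces(
            x, self.mesh.edges[:, 0], self.mesh.edges[:, 1],
            self.lm, self.kp, self.kbt_over_p, f)
        if worst >= 0:
            raise WLCDivergenceError(
                f"edge {worst} at or beyond its maximum extension")
        return e, f

    def bending(self, x: np.ndarray | None = None):
        x = self.mesh.x if x is None else x
        self._check_triangles(x)
        f = np.zeros_like(x)
        e = _kernels.bending_forces(
            x, self.mesh.edges[:, 0], self.mesh.edges[:, 1],
            self.mesh.edge_opposite[:, 0], self.mesh.edge_opposite[:, 1],
            self.kb, self.theta0, f)
        return e, f

    def area_volume(self, x: np.ndarray | None = None):
        x = self.mesh.x if x is None else x
        f = np.zeros_like(x)
        pr = self.params
        area, vol = _kernels.cell_area_volume(x, self.mesh.triangles,
                                              self.tri_cell, 1)
        e = _kernels.area_volume_forces(
            x, self.mesh.triangles, self.tri_cell, self.mesh.a0_tri,
            np.array([pr.k_a]), np.array([pr.k_v]), np.array([pr.k_d]),
            np.array([self.mesh.A0tot]), np.array([self.mesh.V0tot]),
            area, vol, f)
        return e, f

    def total(self, x: np.ndarray | None = None):
        """Total free energy V_t with a per-term breakdown and the total
        force (exact negative gradient)."""
        x = self.mesh.x if x is None else x
        es, fs = self.elastic(x)
        eb, fb = self.bending(x)
        ea, fa = self.area_volume(x)
        return {"elastic": es, "bending": eb, "area_volume": ea,
                "total": es + eb + ea}, fs + fb + fa

    def _check_triangles(self, x: np.ndarray) -> None:
        areas = triangle_areas(x, self.mesh.triangles)
        bad = np.flatnonzero(areas < 1e-12)
        if bad.size:
            raise DegenerateTriangleError(
                f"triangle {bad[0]} has (numerically) zero area")


def total_free_energy(mesh: TriangulatedMembrane,
                      params: CellModelParams) -> dict:
    """Convenience wrapper: V_t = V_s + V_b + V_a + V_v with breakdown."""
    energies, _ = MembraneForceField(mesh, params).total()
    return energies
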