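"""Inter-cell and cell-fluid interactions.

RBC-RBC adhesion (fibrinogen-mediated rouleaux formation) uses a Morse
potential between membrane vertices of distinct RBCs::

    V_M(r) = D_e [ e^{2 beta (r0 - r)} - 2 e^{beta (r0 - r)} ]

with well depth D_e at the zero-force distance r0 and inverse range beta.
All RBC vertices are adhesive by default (the high-fibrinogen limit); the
adhesive fraction is kept as a parameter for future concentration-dependence
studies.  Platelets adhere to nothing: they interact with other cells only
through short-range DPD repulsion.

Solvent couples to membranes through the dissipative/random DPD rows of the
interaction matrix (no-slip at the membrane) while impermeability is
enforced geometrically: solvent particles bounce back off membrane faces,
with the impulse delivered to the face's vertices (momentum conserving).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from . import _kernels
from .dpd import RBC, PLATELET, SOLVENT, WALL, DPDParams, ParticleSystem


@dataclass
class MorseParams:
    """Morse adhesion constants (model units: lengths in um, energies kBT)."""

    De: float = 4.0
    beta: float = 8.5
    r0: float = 0.5
    r_cut: float = 1.4
    enabled: bool = True
    adhesive_fraction: float = 1.0  # all RBC vertices adhesive

    def __post_init__(self) -> None:
        if min(self.De, self.beta, self.r0, self.r_cut) <= 0:
            raise ValueError("Morse constants must be positive")
        if self.r_cut <= self.r0:
            raise ValueError("cutoff must exceed the zero-force distance")

    def tail_magnitude(self) -> float:
        """|V_M(r_cut)| / D_e -- must be negligible (< 1e-3 by default)."""
        e = math.exp(self.beta * (self.r0 - self.r_cut))
        return abs(e * e - 2.0 * e)


def morse_potential(r: float, p: MorseParams, shifted: bool = True) -> float:
    """Morse pair energy; clamped to zero beyond the cutoff with a
    continuity shift when ``shifted``."""
    r = float(r)
    if r <= 0:
        raise ValueError("separation must be positive")
    if r >= p.r_cut:
        return 0.0
    e = math.exp(p.beta * (p.r0 - r))
    v = p.De * (e * e - 2.0 * e)
    if shifted:
        ec = math.exp(p.beta * (p.r0 - p.r_cut))
        v -= p.De * (ec * ec - 2.0 * ec)
    return v


def morse_force(r_vec, p: MorseParams) -> np.ndarray:
    """Central force on the first particle: repulsive inside r0, attractive
    between r0 and the cutoff, zero beyond."""
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise ValueError("zero-length separation vector")
    if r >= p.r_cut:
        return np.zeros(3)
    e = math.exp(p.beta * (p.r0 - r))
    fmag = 2.0 * p.De * p.beta * (e * e - e)  # -dV/dr
    return fmag * r_vec / r


@dataclass
class InteractionMatrix:
    """Per-type-pair interaction assignment.

    DPD applies to every pair (with the coefficient matrices of
    :class:`~mavessel.dpd.DPDParams`); Morse adhesion is layered on top for
    RBC-RBC vertex pairs belonging to different cells when enabled.
    Wall-wall pairs and intra-cell pairs are excluded entirely (the membrane
    network governs intra-cell mechanics).
    """

    dpd: DPDParams = field(default_factory=DPDParams)
    morse: MorseParams = field(default_factory=MorseParams)

    def kind(self, t1: int, t2: int) -> str:
        if t1 == WALL and t2 == WALL:
            return "none"
        if {t1, t2} == {RBC} and self.morse.enabled:
            return "morse+dpd"
        return "dpd"

    def pair_cutoff(self) -> float:
        return max(self.dpd.r_c,
                   self.morse.r_cut if self.morse.enabled else 0.0)

    def morse_mask(self, ptype: np.ndarray, pi: np.ndarray,
                   pj: np.ndarray) -> np.ndarray:
        """Pairs (already excluding intra-cell) eligible for Morse."""
        if not self.morse.enabled:
            return np.zeros(len(pi), dtype=np.bool_)
        return (ptype[pi] == RBC) & (ptype[pj] == RBC)


class UnknownCellError(KeyError):
    """A membrane particle carries a cell id with no registered cell."""


def intercell_pair_forces(system: ParticleSystem, matrix: InteractionMatrix,
                          n_cells: int | None = None) -> np.ndarray:
    """Conservative intercellular forces (cross-cell short-range repulsion
    plus Morse adhesion where applicable) on every particle.

    Dissipative/random DPD terms are omitted here: this is the static
    inter-membrane force field used for doublet/aggregation analysis.  The
    full simulation adds the thermal terms in the driver loop.
    """
    membrane = np.isin(system.ptype, (RBC, PLATELET))
    if n_cells is not None:
        known = set(range(n_cells))
        bad = set(np.unique(system.cell_id[membrane])) - known
        if bad:
            raise UnknownCellError(f"membrane particles with unknown cell "
                                   f"ids {sorted(bad)}")
    cut = matrix.pair_cutoff()
    pi, pj = _kernels.build_pair_list(system.x, system.ptype, system.cell_id,
                                      system.n, system.box.lo, system.box.hi,
                                      cut, system.box.periodic)
    # cross-cell membrane-membrane pairs only
    mm = membrane[pi] & membrane[pj] \
        & (system.cell_id[pi] != system.cell_id[pj])
    pi, pj = pi[mm], pj[mm]
    forces = np.zeros_like(system.x)
    mask = matrix.morse_mask(system.ptype, pi, pj)
    intra = np.zeros(len(pi), dtype=np.bool_)
    d = matrix.dpd
    _kernels.pair_forces_from_list(
        system.x, np.zeros_like(system.v), system.ptype, pi, pj, intra,
        system.box.lo, system.box.hi, system.box.periodic,
        d.a, np.zeros_like(d.gamma), np.zeros_like(d.sigma), d.s, d.r_c,
        0.0, 0.0,
        mask, matrix.morse.De, matrix.morse.beta, matrix.morse.r0,
        matrix.morse.r_cut, 0, 0, 1.0, forces)
    return forces


def reflect_solvent_at_membranes(system: ParticleSystem, xprev: np.ndarray,
                                 triangles: np.ndarray, grid_cut: float,
                                 vcap: float = 1e30) -> int:
    """Bounce solvent particles off membrane faces crossed during the last
    position update (impermeability); returns the reflection count."""
    flags = np.zeros(system.n, dtype=np.uint8)
    return _kernels.membrane_reflect(
        system.x, system.v, xprev, system.ptype, system.n, triangles,
        system.x, system.x, triangles.shape[0], system.box.lo,
        system.box.hi, system.box.periodic, grid_cut, vcap, flags)
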