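"""Validation scenarios (synthetic-data generators).

Every physics claim of the package is testable from these self-contained
fixtures with no external data: a periodic thermal box (thermostat and
momentum), a plain rectangular duct (no-slip walls, Poiseuille profile,
drive controller), a single-RBC stretching test (membrane elasticity), an
RBC doublet (Morse adhesion) and the scaled-down MA channel scenarios
(transport trends).

Desk scale: the mini-MA fixtures keep the study's geometry ratios,
hematocrit levels and physical drive velocities but reduce the solvent
density (0.75 instead of 3 per cubic micrometre), use coarse RBC meshes
(N_v = 66) and short channels/runs, so each completes in minutes on one
CPU.  Absolute probabilities and times at this scale differ from the
full-scale study; orderings across conditions are the comparable output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .driver import SimulationConfig
from .dpd import DPDParams
from .geometry import FlowDrive
from .interactions import MorseParams

#: desk-scale knobs shared by all mini fixtures
MINI_DENSITY = 0.75
MINI_DT = 0.01
MINI_RBC_NV = 66
MINI_LENGTH_UM = 18.0
MINI_STEPS = 5_000
MINI_EQUIL = 2_000


@dataclass(frozen=True)
class FixtureSpec:
    """A named fixture plus the properties it is meant to check."""

    name: str
    config: SimulationConfig
    checks: tuple[str, ...] = ()


def make_thermal_box(seed: int = 0, L: float = 5.0,
                     n_steps: int = 12_000) -> SimulationConfig:
    """Periodic solvent-only cube, no walls, no drive: validates the
    thermostat (temperature within 5% of kBT) and momentum conservation.

    The returned config is interpreted by the test harness through the raw
    kernels (no channel geometry); ``bnr``/geometry fields are unused.
    """
    return SimulationConfig(
        bnr=1.0, neck_width=5.0, length=L, hematocrit=0.0,
        dpd=DPDParams(density=3.0, dt=0.01),
        platelet_rate_per_s=0.0,
        n_steps=n_steps, equil_steps=0, output_every=max(n_steps // 50, 1),
        seed=seed, label=f"thermal-box-L{L}")


def make_poiseuille_slab(target_mm_per_s: float = 1.5, seed: int = 0,
                         n_steps: int = 16_000,
                         length: float = 10.0) -> SimulationConfig:
    """Straight rectangular duct with the parent-channel cross-section
    (5 x 10 um), no cells: validates no-slip walls, the analytic duct
    profile and the closed-loop drive controller."""
    return SimulationConfig(
        bnr=1.0, neck_width=0.5, length=length, hematocrit=0.0,
        dpd=DPDParams(density=3.0, dt=0.01),
        platelet_rate_per_s=0.0,
        drive=FlowDrive(target_mm_per_s=target_mm_per_s),
        n_steps=n_steps, equil_steps=0,
        output_every=max(n_steps // 100, 1),
        seed=seed, label="poiseuille-slab")


def make_rbc_stretch(seed: int = 0, diabetic: bool = False) -> dict:
    """Single-RBC optical-tweezers-style stretching test parameters.

    Returned as a parameter dict (no solvent, no channel): the test harness
    applies opposing point loads to the outermost vertex groups and relaxes
    the membrane; axial diameter must grow monotonically with load and the
    diabetic preset (5x shear modulus) must stretch less.
    """
    return {
        "preset": "rbc_diabetic" if diabetic else "rbc_normal",
        "n_vertices": 200,
        "load_fraction": 0.05,   # vertex fraction per grip
        "loads_model": (0.0, 50.0, 100.0, 200.0),
        "relax_steps": 3000,
        "dt": 0.004,
        "seed": seed,
    }


def make_adhesion_doublet(adhesion_on: bool, seed: int = 0,
                          n_steps: int = 3_000) -> SimulationConfig:
    """Two RBCs at near-contact in quiescent solvent: adhesion ON keeps
    the doublet together, OFF lets thermal motion separate it.

    The box is sized so the seeding routine places exactly two face-on
    cells whose gap lies inside the Morse attraction range."""
    return SimulationConfig(
        bnr=1.0, neck_width=0.5, length=8.0, r2=9.0, depth=9.0,
        hematocrit=0.287,        # exactly two cells in the 8x9x9 duct
        dpd=DPDParams(density=1.0, dt=MINI_DT),
        rbc_n_vertices=MINI_RBC_NV,
        morse=MorseParams(enabled=adhesion_on),
        platelet_rate_per_s=0.0,
        drive=FlowDrive(target_mm_per_s=1e-6),  # quiescent
        n_steps=n_steps, equil_steps=1_500,
        output_every=max(n_steps // 60, 1),
        seed=seed, label=f"doublet-{'on' if adhesion_on else 'off'}")


def make_mini_ma(bnr: float, hematocrit: float, velocity_mm_per_s: float,
                 adhesion: bool = False, diabetic: bool = False,
                 pulsatile: bool = False, seed: int = 0,
                 n_steps: int = MINI_STEPS,
                 length: float = MINI_LENGTH_UM,
                 equil_steps: int = MINI_EQUIL) -> SimulationConfig:
    """Scaled-down MA-channel scenario at true geometry ratios.

    ``bnr`` is one of the four study values (2.2, 3, 5.4, 8); hematocrit
    one of 10/20/40%.  RBCs seed in the parent vessel; platelets flow in
    from the inlet.
    """
    if bnr not in (2.2, 3.0, 5.4, 8.0):
        raise ValueError("bnr must be one of the four study values")
    if round(hematocrit, 2) not in (0.10, 0.20, 0.40):
        raise ValueError("hematocrit must be 10, 20 or 40%")
    return SimulationConfig(
        bnr=bnr, length=length, hematocrit=hematocrit,
        dpd=DPDParams(density=MINI_DENSITY, dt=MINI_DT),
        rbc_n_vertices=MINI_RBC_NV,
        rbc_preset="rbc_diabetic" if diabetic else "rbc_normal",
        morse=MorseParams(enabled=adhesion),
        platelet_rate_per_s=600.0,
        seeding="parent",
        drive=FlowDrive(mode="pulsatile" if pulsatile else "static",
                        target_mm_per_s=velocity_mm_per_s,
                        amplitude_fraction=0.3 if pulsatile else 0.0),
        n_steps=n_steps, equil_steps=equil_steps,
        output_every=25, seed=seed,
        label=f"mini-ma-bnr{bnr}-ht{int(hematocrit * 100)}"
              f"-v{velocity_mm_per_s}"
              f"{'-adh' if adhesion else ''}{'-stiff' if diabetic else ''}")


def fixture_suite(fast: bool = True) -> list[FixtureSpec]:
    """The named validation fixtures and what each one checks."""
    out = [
        FixtureSpec("thermal-box", make_thermal_box(0),
                    ("temperature within 5% of kBT",
                     "momentum conserved")),
        FixtureSpec("poiseuille", make_poiseuille_slab(1.5, 0),
                    ("no-slip duct profile < 10% RMS vs analytic",
                     "controller converges to target")),
        FixtureSpec("doublet-on", make_adhesion_doublet(True, 0),
                    ("adhesive doublet persists",)),
        FixtureSpec("doublet-off", make_adhesion_doublet(False, 0),
                    ("non-adhesive doublet separates",)),
    ]
    if not fast:
        out.append(FixtureSpec(
            "mini-ma-smallest", make_mini_ma(2.2, 0.20, 1.5, seed=0),
            ("at least one platelet passage", "metrics deterministic")))
    return out
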