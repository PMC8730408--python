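"""Microaneurysm (MA) channel geometry and flow driving.

The channel is a rectangular parent capillary (width R2 = 5 um along y,
depth 10 um along z, periodic along x) with a saccular MA body attached to
the y = R2 wall face: a sphere of diameter R1 = BNR * R2 truncated by the
wall plane, communicating with the duct through a circular neck opening of
width ~15 um (clamped to R1 for small bodies).  The lumen is

    parent :  0 < y < R2,  0 < z < depth
    body   :  y >= R2  and  |p - c| < R1/2

with the sphere center placed at height sqrt((R1/2)^2 - (neck/2)^2) above
the wall plane, so the neck disk cut by y = R2 has exactly the requested
width.  The neck surface (the disk) is the event-detection boundary between
the two lumen regions.

Flow is driven by a uniform body force on solvent particles in the parent
duct (equivalent to a pressure gradient under x-periodicity), closed-loop
tuned by a proportional-integral controller to a target mean inlet velocity,
optionally modulated sinusoidally for pulsatile flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from . import _kernels

PARENT, MA_BODY, OUTSIDE = "parent", "ma_body", "outside"

#: the four MA sizes studied, as body-to-neck ratios
STUDY_BNRS = (2.2, 3.0, 5.4, 8.0)
DEFAULT_R2_UM = 5.0
DEFAULT_DEPTH_UM = 10.0
DEFAULT_NECK_UM = 15.0


@dataclass(frozen=True)
class MAChannelGeometry:
    """Parent duct + truncated-sphere saccular body (all lengths in um)."""

    bnr: float
    r2: float = DEFAULT_R2_UM
    depth: float = DEFAULT_DEPTH_UM
    length: float = 0.0           # 0 -> auto
    neck_width: float = DEFAULT_NECK_UM

    def __post_init__(self) -> None:
        if self.bnr < 1.0:
            raise ValueError("BNR must be >= 1")
        if self.neck_width > self.R1 + 1e-12:
            raise ValueError("neck opening cannot be wider than the MA body")
        if self.length and self.length <= self.neck_width:
            raise ValueError("channel length must exceed the neck width")

    @property
    def R1(self) -> float:
        """MA body diameter, R1 = BNR * R2."""
        return self.bnr * self.r2

    @property
    def body_radius(self) -> float:
        return self.R1 / 2.0

    @property
    def L(self) -> float:
        """Channel length; defaults to 4*max(R1, neck)/2 + 20 so the MA's
        periodic image stays clear of its own wake."""
        if self.length:
            return self.length
        return 4.0 * max(self.R1, self.neck_width) + 20.0

    @property
    def neck_radius(self) -> float:
        return self.neck_width / 2.0

    @property
    def body_center(self) -> np.ndarray:
        h = math.sqrt(max(self.body_radius**2 - self.neck_radius**2, 0.0))
        return np.array([self.L / 2.0, self.r2 + h, self.depth / 2.0])

    @property
    def parent_volume(self) -> float:
        return self.L * self.r2 * self.depth

    @property
    def body_volume(self) -> float:
        """Spherical-cap volume of the lumen part above the wall plane."""
        rho = self.body_radius
        h = self.body_center[1] - self.r2
        cap_h = rho + h
        return math.pi * cap_h**2 * (3.0 * rho - cap_h) / 3.0

    @property
    def lumen_volume(self) -> float:
        return self.parent_volume + self.body_volume

    def bounding_box(self, pad: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        c = self.body_center
        rho = self.body_radius
        lo = np.array([0.0, -pad, min(-pad, c[2] - rho - pad)])
        hi = np.array([self.L,
                       max(self.r2 + pad, c[1] + rho + pad),
                       max(self.depth + pad, c[2] + rho + pad)])
        return lo, hi

    # -- predicates --------------------------------------------------------
    def classify_point(self, p) -> str:
        """parent | ma_body | outside (wall material)."""
        p = np.asarray(p, dtype=float)
        c = self.body_center
        code = _kernels.lumen_code(p[0], p[1], p[2], self.r2, self.depth,
                                   c[0], c[1], c[2], self.body_radius)
        return (PARENT, MA_BODY, OUTSIDE)[code if code >= 0 else 2]

    def classify_points(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized classification: 0 parent, 1 body, -1 outside."""
        pts = np.asarray(pts, dtype=float)
        c = self.body_center
        parent = (pts[:, 1] > 0) & (pts[:, 1] < self.r2) \
            & (pts[:, 2] > 0) & (pts[:, 2] < self.depth)
        body = (~parent) & (pts[:, 1] >= self.r2) \
            & (((pts - c)**2).sum(axis=1) < self.body_radius**2)
        out = np.full(len(pts), -1, dtype=np.int64)
        out[parent] = 0
        out[body] = 1
        return out

    def in_lumen(self, pts: np.ndarray) -> np.ndarray:
        return self.classify_points(pts) >= 0

    # -- wall particles ----------------------------------------------------
    def generate_wall_particles(self, thickness: float, density: float,
                                fluid_cutoff: float = 1.0,
                                seed: int = 0) -> np.ndarray:
        """Frozen particles filling a shell of the given thickness outside
        the lumen (jittered lattice at the requested number density).

        Combined with solvent bounce-back at the lumen surface this is the
        no-slip wall recipe; thickness below the fluid cutoff would let the
        fluid see vacuum through the wall.
        """
        if thickness < fluid_cutoff:
            raise ValueError("wall shell thinner than the fluid cutoff")
        rng = np.random.default_rng(seed)
        t = thickness
        lo, hi = self.bounding_box(pad=t)
        spacing = density ** (-1.0 / 3.0)
        axes = [np.arange(lo[ax] + spacing / 2, hi[ax], spacing)
                for ax in range(3)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        pts = pts.reshape(-1, 3)
        pts = pts + rng.uniform(-0.3 * spacing, 0.3 * spacing, pts.shape)
        pts[:, 0] %= self.L
        c = self.body_center
        in_lumen = self.in_lumen(pts)
        near_duct = (pts[:, 1] > -t) & (pts[:, 1] < self.r2 + t) \
            & (pts[:, 2] > -t) & (pts[:, 2] < self.depth + t)
        near_body = (pts[:, 1] >= self.r2 - t) \
            & (((pts - c)**2).sum(axis=1) < (self.body_radius + t)**2)
        keep = ~in_lumen & (near_duct | near_body)
        return pts[keep]


def build_ma_channel(bnr: float, r2: float = DEFAULT_R2_UM,
                     depth: float = DEFAULT_DEPTH_UM,
                     neck_width: float | None = None,
                     length: float = 0.0) -> MAChannelGeometry:
    """Construct the MA channel for a given body-to-neck ratio.

    The default neck opening is 15 um, clamped to the body diameter for
    small bodies (a neck as wide as the body degenerates to a hemispherical
    side pocket).
    """
    R1 = bnr * r2
    if neck_width is None:
        neck_width = min(DEFAULT_NECK_UM, R1)
    return MAChannelGeometry(bnr=bnr, r2=r2, depth=depth, length=length,
                             neck_width=neck_width)


# ---------------------------------------------------------------------------
# flow drive


@dataclass
class FlowDrive:
    """Target mean inlet velocity and (optional) sinusoidal pulsatility."""

    mode: str = "static"               # static | pulsatile
    target_mm_per_s: float = 1.5
    amplitude_fraction: float = 0.0
    period_s: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("static", "pulsatile"):
            raise ValueError("mode must be static or pulsatile")
        if self.target_mm_per_s <= 0:
            raise ValueError("target velocity must be positive")
        if not (0.0 <= self.amplitude_fraction < 1.0):
            raise ValueError("amplitude fraction must lie in [0, 1)")


def pulsatile_modulation(drive: FlowDrive, t: float,
                         period: float | None = None) -> float:
    """Instantaneous force scale 1 + A sin(2 pi t / T); averages to exactly
    1 over an integer number of periods.  ``t`` and ``period`` share units
    (model time when ``period`` is given, seconds otherwise)."""
    if drive.mode == "static" or drive.amplitude_fraction == 0.0:
        return 1.0
    T = drive.period_s if period is None else period
    if T <= 0:
        raise ValueError("pulsatile period must be positive")
    return 1.0 + drive.amplitude_fraction * math.sin(2.0 * math.pi * t / T)


class BodyForceController:
    """Discrete proportional-integral tuner of the driving body force.

    The measured mean inlet velocity (trailing window) is compared with the
    target; the force magnitude is nudged proportionally plus an integral
    term.  Non-finite measurements hold the previous force.
    """

    def __init__(self, target_velocity: float, g0: float,
                 kp_rel: float = 0.6, ki_rel: float = 0.25):
        if target_velocity <= 0:
            raise ValueError("target velocity must be positive")
        self.target = target_velocity
        self.g = g0
        self.kp = kp_rel * g0 / target_velocity
        self.ki = ki_rel * g0 / target_velocity
        self.prev_err = 0.0
        self.held = 0

    def update(self, measured_velocity: float) -> float:
        if not math.isfinite(measured_velocity):
            self.held += 1
            return self.g
        err = self.target - measured_velocity
        # velocity-form PI: proportional on the error change, integral on
        # the error itself (the force is the integrator state)
        self.g = max(0.0, self.g + self.kp * (err - self.prev_err)
                     + self.ki * err)
        self.prev_err = err
        return self.g


def initial_body_force(target_velocity: float, width: float,
                       kinematic_viscosity: float = 0.8) -> float:
    """Plane-Poiseuille first guess g = 12 nu v / W^2 for the controller."""
    return 12.0 * kinematic_viscosity * target_velocity / width**2
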