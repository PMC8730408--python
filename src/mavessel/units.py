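"""Model <-> physical unit mapping.

DPD simulations are run in reduced units.  The mapping is anchored by three
scales: a length (how many micrometres one model length unit represents), an
energy (anchored to the thermal energy k_B*T at body temperature) and a mass.
The time scale is *derived*, not free::

    time_scale = length_scale * sqrt(mass_scale / energy_scale)

which is the classical MD/DPD convention.  With the defaults below one model
length unit is 1 um, one energy unit is k_B*T at 310 K, and the mass scale is
chosen so that one model velocity unit corresponds to 2.5 mm/s -- placing
the physiological capillary velocities (0.25-2.0 mm/s) below the DPD
thermal velocity while keeping advection well above the exaggerated
coarse-grained diffusion (a realistically large Peclet number).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

#: Boltzmann constant times 310 K, in joules.
KBT_310K = 1.380649e-23 * 310.0


@dataclass(frozen=True)
class UnitSystem:
    """Conversion factors between model units and SI.

    Parameters
    ----------
    length_um:
        Micrometres per model length unit.
    energy_J:
        Joules per model energy unit (default: k_B*T at 310 K).
    mass_kg:
        Kilograms per model mass unit.
    """

    length_um: float = 1.0
    energy_J: float = KBT_310K
    mass_kg: float = 6.8532e-16

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.energy_J <= 0 or self.mass_kg <= 0:
            raise ValueError("all unit scales must be strictly positive")

    # -- derived scales ----------------------------------------------------
    @property
    def length_m(self) -> float:
        return self.length_um * 1e-6

    @property
    def time_s(self) -> float:
        """Seconds per model time unit (derived combination)."""
        return self.length_m * math.sqrt(self.mass_kg / self.energy_J)

    @property
    def velocity_m_per_s(self) -> float:
        return self.length_m / self.time_s

    @property
    def force_N(self) -> float:
        return self.energy_J / self.length_m

    # -- conversions -------------------------------------------------------
    def to_model_length(self, um: float) -> float:
        return um / self.length_um

    def to_um(self, model_length: float) -> float:
        return model_length * self.length_um

    def to_model_velocity(self, mm_per_s: float) -> float:
        return (mm_per_s * 1e-3) / self.velocity_m_per_s

    def to_mm_per_s(self, model_velocity: float) -> float:
        return model_velocity * self.velocity_m_per_s * 1e3

    def to_model_time(self, seconds: float) -> float:
        return seconds / self.time_s

    def to_seconds(self, model_time: float) -> float:
        return model_time * self.time_s

    def to_model_shear_modulus(self, uN_per_m: float) -> float:
        """Convert a 2D shear modulus (uN/m) to model energy/length^2."""
        return (uN_per_m * 1e-6) / (self.energy_J / self.length_m**2)

    def to_model_energy(self, joules: float) -> float:
        return joules / self.energy_J


DEFAULT_UNITS = UnitSystem()
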