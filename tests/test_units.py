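import math

import pytest
from hypothesis import given, strategies as st

from mavessel.units import KBT_310K, UnitSystem


def test_time_scale_is_derived_combination():
    u = UnitSystem(length_um=1.0, energy_J=KBT_310K, mass_kg=1.7133e-16)
    assert u.time_s == pytest.approx(
        u.length_m * math.sqrt(u.mass_kg / u.energy_J), rel=1e-14)


def test_default_mapping_puts_capillary_velocities_below_thermal():
    # 0.25-2.0 mm/s must map well below the unit thermal velocity
    u = UnitSystem()
    assert 0.02 < u.to_model_velocity(0.25) < u.to_model_velocity(2.0) < 0.9


@given(st.floats(0.1, 100.0), st.floats(1e-22, 1e-18),
       st.floats(1e-18, 1e-14))
def test_round_trip_is_identity(length, energy, mass):
    u = UnitSystem(length_um=length, energy_J=energy, mass_kg=mass)
    for v in (0.37, 1.5):
        assert u.to_mm_per_s(u.to_model_velocity(v)) == pytest.approx(v)
        assert u.to_um(u.to_model_length(v)) == pytest.approx(v)
        assert u.to_seconds(u.to_model_time(v)) == pytest.approx(v)


@pytest.mark.parametrize("kwargs", [
    dict(length_um=0.0), dict(energy_J=-1.0), dict(mass_kg=0.0)])
def test_nonpositive_scales_rejected(kwargs):
    with pytest.raises(ValueError):
        UnitSystem(**kwargs)
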