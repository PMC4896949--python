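import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from magshield.constants import AMU, PROTON_MASS
from magshield.materials import ALUMINUM, WATER
from magshield.physics import (
    ParticleState,
    dedx_ionization,
    deflection_angle,
    gyroradius,
    let_water,
    quality_factor,
    rigidity,
)


class TestRigidity:
    def test_zero_energy_gives_zero_rigidity(self):
        assert rigidity(0.0, 1, 1) == 0.0
        assert rigidity(0.0, 26, 56) == 0.0

    def test_proton_1gev(self):
        # sqrt(1000*(1000+2*938.272))/1000
        expected = math.sqrt(1000.0 * (1000.0 + 2 * PROTON_MASS)) / 1000.0
        assert rigidity(1000.0, 1, 1) == pytest.approx(expected, rel=1e-12)
        assert rigidity(1000.0, 1, 1) == pytest.approx(1.696, abs=5e-4)

    def test_helium_scales_as_a_over_z(self):
        # per-nucleon rest mass 931.494 for A > 1
        expected = 4 * math.sqrt(1000.0 * (1000.0 + 2 * AMU)) / (2 * 1000.0)
        r_he = rigidity(1000.0, 2, 4)
        assert r_he == pytest.approx(expected, rel=1e-12)
        # ~ twice the proton value (within the rest-mass convention)
        assert r_he == pytest.approx(2 * rigidity(1000.0, 1, 1), rel=3e-3)

    def test_rest_mass_override(self):
        r = rigidity(1000.0, 2, 4, rest_energy=PROTON_MASS)
        assert r == pytest.approx(2 * rigidity(1000.0, 1, 1), rel=1e-12)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            rigidity(-1.0, 1, 1)

    @given(e=st.floats(1.0, 1e5), e2=st.floats(1.0, 1e5))
    def test_strictly_increasing_in_energy(self, e, e2):
        lo, hi = min(e, e2), max(e, e2)
        if lo < hi:
            assert rigidity(lo, 6, 12) < rigidity(hi, 6, 12)

    def test_increasing_in_a_over_z(self):
        # at fixed E, larger A/Z means larger rigidity
        assert rigidity(500.0, 26, 56) > rigidity(500.0, 26, 52)
        assert rigidity(500.0, 2, 4) > rigidity(500.0, 3, 6) * 0.99999


class TestStoppingPower:
    def test_charge_squared_scaling_exact(self):
        beta = 0.7
        d1 = dedx_ionization(1, beta, WATER)
        d2 = dedx_ionization(2, beta, WATER)
        assert d2 / d1 == pytest.approx(4.0, rel=1e-12)

    def test_proton_water_minimum_ionizing(self):
        # beta*gamma = 3 -> beta = 3/sqrt(10); direct evaluation with
        # I = 75 eV gives ~2.0 MeV cm^2/g
        beta = 3.0 / math.sqrt(10.0)
        assert dedx_ionization(1, beta, WATER) == pytest.approx(2.0, rel=0.03)

    def test_low_velocity_dominance(self):
        assert dedx_ionization(1, 0.1, WATER) > dedx_ionization(1, 0.2, WATER)

    def test_inverse_beta_squared_dominates_at_low_velocity(self):
        # with delta = 0, halving beta below 0.3 raises dE/dx close to the
        # 1/beta^2 prefactor; the slowly varying logarithm tempers the
        # exact factor of 4 by ~20%
        from dataclasses import replace
        water0 = replace(WATER, sternheimer=None, I_eff=75.0)
        ratio = dedx_ionization(1, 0.15, water0) / dedx_ionization(1, 0.30, water0)
        assert 3.0 < ratio < 4.0

    def test_beta_bounds_rejected(self):
        for beta in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                dedx_ionization(1, beta, WATER)

    def test_aluminum_below_water(self):
        # lower Z/A and higher I make Al stop less per unit mass
        assert dedx_ionization(1, 0.9, ALUMINUM) < dedx_ionization(1, 0.9, WATER)


class TestLET:
    def test_unit_conversion_identity(self):
        beta = 0.8
        assert let_water(3, beta) == pytest.approx(
            dedx_ionization(3, beta, WATER) / 10.0, rel=1e-12)

    def test_monotone_in_charge(self):
        lets = [let_water(z, 0.5) for z in (1, 2, 6, 14, 26)]
        assert all(a < b for a, b in zip(lets, lets[1:]))


class TestQualityFactor:
    @pytest.mark.parametrize("L,expected", [
        (0.0, 1.0), (5.0, 1.0), (10.0, 1.0),
        (50.0, 12.8),            # 0.32*50 - 3.2
        (300.0, 1.0),            # 300/300
        (100.0, 3.0),            # 300/100
    ])
    def test_printed_form(self, L, expected):
        assert quality_factor(L) == pytest.approx(expected, rel=1e-12)

    def test_continuous_at_ten(self):
        # middle branch extrapolates to 0.32*10 - 3.2 = 0 at L = 10
        assert quality_factor(10.0 + 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_discontinuity_at_hundred_preserved(self):
        below = quality_factor(100.0 - 1e-9)   # ~28.8
        at = quality_factor(100.0)             # 3.0
        assert below == pytest.approx(28.8, abs=1e-6)
        assert at == pytest.approx(3.0, rel=1e-12)
        assert below - at > 25.0

    def test_icrp60_mode(self):
        assert quality_factor(50.0, "icrp60") == pytest.approx(13.8)
        assert quality_factor(400.0, "icrp60") == pytest.approx(15.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            quality_factor(-1.0)


class TestDeflection:
    def test_zero_field(self):
        assert deflection_angle(0.0, 1.0) == 0.0

    def test_printed_example(self):
        assert deflection_angle(4.0, 1.696) == pytest.approx(0.707, abs=1e-3)

    @given(r=st.floats(0.1, 100.0), r2=st.floats(0.1, 100.0))
    def test_monotone_decreasing_in_rigidity(self, r, r2):
        lo, hi = min(r, r2), max(r, r2)
        if lo < hi:
            assert deflection_angle(4.0, lo) > deflection_angle(4.0, hi)

    def test_zero_rigidity_rejected(self):
        with pytest.raises(ValueError):
            deflection_angle(4.0, 0.0)

    def test_gyroradius_example(self):
        assert gyroradius(1.696, 1, 1.0) == pytest.approx(5.66, abs=0.01)


class TestParticleState:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ParticleState(Z=0, A=1, E=1.0, position=np.zeros(3),
                          direction=np.array([0, 0, 1.0]))
        with pytest.raises(ValueError):
            ParticleState(Z=2, A=1, E=1.0, position=np.zeros(3),
                          direction=np.array([0, 0, 1.0]))
        with pytest.raises(ValueError):
            ParticleState(Z=1, A=1, E=1.0, position=np.zeros(3),
                          direction=np.array([0, 0, 2.0]))

    def test_kinematics_consistency(self):
        s = ParticleState(Z=1, A=1, E=1000.0, position=np.zeros(3),
                          direction=np.array([0, 0, 1.0]))
        assert s.gamma == pytest.approx(1.0 + 1000.0 / PROTON_MASS)
        assert s.momentum == pytest.approx(1696.0, abs=0.1)
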