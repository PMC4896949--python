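import math

import numpy as np
import pytest

from magshield.fields import FieldMap, FieldRegion
from magshield.fixtures import build_fixture
from magshield.geometry import Box, Cylinder, GeometryModel
from magshield.materials import ALUMINUM, WATER
from magshield.physics import ParticleState
from magshield.source import PrimarySample
from magshield.transport import (
    TransportSettings,
    bradt_peters_sigma,
    interaction_length,
    propagate,
    step_in_field,
    toy_nuclear_interaction,
)


def proton(E=1000.0, pos=(0, 0, 0), d=(1.0, 0, 0)):
    return ParticleState(Z=1, A=1, E=E, position=np.array(pos, float),
                         direction=np.array(d, float))


def uniform_z_field(B=1.0, r=1e3):
    return FieldMap([FieldRegion(Cylinder((0, 0, 0), "z", r, r),
                                 "uniform_axial", B)])


class TestFieldStepping:
    def test_zero_field_straight_line(self):
        s = step_in_field(proton(), FieldMap([]), 2.5)
        assert s.position == pytest.approx([2.5, 0, 0])
        assert s.direction == pytest.approx([1, 0, 0])
        assert s.E == 1000.0

    def test_gyroradius_and_reversal(self):
        """A 1.696 GeV/c proton in 1 T has r = 5.66 m; after a path of
        pi*r the direction is reversed."""
        fmap = uniform_z_field(1.0)
        s = proton(E=1000.0)
        rg = s.momentum / 1000.0 / (0.299792458 * 1.0)
        assert rg == pytest.approx(5.66, abs=0.01)
        n = 1000
        for _ in range(n):
            s = step_in_field(s, fmap, math.pi * rg / n)
        assert float(np.dot(s.direction, [1, 0, 0])) == pytest.approx(
            -1.0, abs=1e-6)
        # displaced by the gyro-diameter perpendicular to v0 and B
        assert abs(s.position[1]) == pytest.approx(2 * rg, rel=1e-6)

    def test_helical_pitch_preserved(self):
        fmap = uniform_z_field(2.0)
        d0 = np.array([0.6, 0.0, 0.8])
        s = ParticleState(Z=2, A=4, E=500.0, position=np.zeros(3),
                          direction=d0)
        for _ in range(500):
            s = step_in_field(s, fmap, 0.02)
        assert s.direction[2] == pytest.approx(0.8, rel=1e-9)
        assert np.linalg.norm(s.direction) == pytest.approx(1.0, rel=1e-12)
        assert s.E == 500.0  # magnetic step never changes the energy

    def test_closed_form_helix_over_100_gyroperiods(self):
        """Final position matches the analytic helix to 1e-6 relative."""
        B = 1.0
        s0 = proton(E=1000.0, d=(1.0, 0.0, 0.0))
        rg = s0.momentum / 1000.0 / (0.299792458 * B)
        fmap = uniform_z_field(B)
        total_path = 100 * 2 * math.pi * rg
        n_steps = int(total_path / (0.05 * rg)) + 1
        ds = total_path / n_steps
        s = s0
        for _ in range(n_steps):
            s = step_in_field(s, fmap, ds)
        # positively charged particle circles clockwise seen from +z:
        # x(s) = rg sin(s/rg), y(s) = rg (cos(s/rg) - 1)
        phi = total_path / rg
        expected = np.array([rg * math.sin(phi), rg * (math.cos(phi) - 1.0),
                             0.0])
        scale = 2 * math.pi * rg
        assert np.allclose(s.position, expected, atol=1e-6 * scale)

    def test_reversibility(self):
        """Reversing direction and charge retraces a field-only path."""
        fmap = uniform_z_field(1.5)
        s = ParticleState(Z=6, A=12, E=800.0, position=np.zeros(3),
                          direction=np.array([0.8, 0.36, 0.48]) /
                          np.linalg.norm([0.8, 0.36, 0.48]))
        path = [s]
        for _ in range(200):
            s = step_in_field(s, fmap, 0.05)
            path.append(s)
        # flip direction; with the same charge, flipping B is equivalent
        # to flipping charge
        back = ParticleState(Z=6, A=12, E=800.0,
                             position=s.position.copy(),
                             direction=-s.direction)
        for _ in range(200):
            back = step_in_field(back, fmap.scaled(-1.0), 0.05)
        assert np.allclose(back.position, path[0].position, atol=1e-7 * 10)


class TestPropagation:
    def test_vacuum_only_no_deposits(self):
        fx = build_fixture("free_space")
        s = proton(E=500.0, pos=(-1.5, 1.0, 0.5), d=(1.0, 0, 0))
        dep, fin = propagate(PrimarySample(s, 0, 1.0), fx.geometry, fx.field,
                             TransportSettings(), np.random.default_rng(0),
                             record_all=True)
        assert dep == []
        assert fin.E == 500.0

    def test_energy_bookkeeping(self):
        fx = build_fixture("free_space")
        s = ParticleState(Z=8, A=16, E=800.0,
                          position=np.array([-1.5, 0.05, 0.1]),
                          direction=np.array([1.0, 0, 0]))
        dep, fin = propagate(PrimarySample(s, 0, 1.0), fx.geometry, fx.field,
                             TransportSettings(), np.random.default_rng(0),
                             record_all=True)
        total = sum(d.dE for d in dep)
        assert 800.0 * 16 == pytest.approx(fin.E * 16 + total, rel=1e-6)

    def test_100mev_proton_stops_with_full_deposit(self):
        """CSDA range ~7.7 g/cm^2 is far below the 180-cm phantom length."""
        fx = build_fixture("free_space")
        s = proton(E=100.0, pos=(0, 0, -1.45), d=(0, 0, 1.0))
        dep, fin = propagate(PrimarySample(s, 0, 1.0), fx.geometry, fx.field,
                             TransportSettings(), np.random.default_rng(0),
                             record_all=True)
        assert fin.E == 0.0
        assert sum(d.dE for d in dep) == pytest.approx(100.0, rel=1e-3)
        # and it stopped within ~10 cm of the entry face
        assert all(d.position[2] < -0.50 for d in dep)

    def test_magnetic_shadow(self):
        """With BL large enough that theta exceeds the habitat's angular
        size, barrel primaries of that rigidity no longer reach the
        phantoms directly."""
        fx = build_fixture("sr2s_cct", BL=100.0, box_size=12.0)
        st = TransportSettings()
        rng = np.random.default_rng(1)
        hits = {True: 0, False: 0}
        for strong in (True, False):
            fmap = fx.field if strong else fx.field.scaled(0.0)
            for i in range(300):
                # low-rigidity protons aimed at the habitat center
                y = -6.0 + 1e-6
                x = rng.uniform(-2.0, 2.0)
                d = np.array([0.0, 1.0, 0.0])
                s = proton(E=400.0, pos=(x, y, 0.0), d=tuple(d))
                dep, _ = propagate(PrimarySample(s, 0, 1.0), fx.geometry,
                                   fmap, st, rng)
                hits[strong] += len(dep) > 0
        assert hits[True] < hits[False] * 0.2


class TestToyNuclearModel:
    def test_disabled_model_bitwise_identical(self):
        fx = build_fixture("free_space")
        s1 = proton(E=300.0, pos=(0, 0, -1.45), d=(0, 0, 1.0))
        s2 = proton(E=300.0, pos=(0, 0, -1.45), d=(0, 0, 1.0))
        st = TransportSettings(nuclear=False)
        d1, f1 = propagate(PrimarySample(s1, 0, 1.0), fx.geometry, fx.field,
                           st, np.random.default_rng(5), record_all=True)
        d2, f2 = propagate(PrimarySample(s2, 0, 1.0), fx.geometry, fx.field,
                           st, np.random.default_rng(99), record_all=True)
        assert [d.dE for d in d1] == [d.dE for d in d2]
        assert toy_nuclear_interaction(s1, WATER, np.random.default_rng(0),
                                       st) == []

    def test_sigma_monotone_in_target_mass(self):
        sigmas = [bradt_peters_sigma(1, a) for a in (1, 12, 27, 56, 207)]
        assert all(a < b for a, b in zip(sigmas, sigmas[1:]))

    def test_interaction_length_reasonable(self):
        lam = interaction_length(1, ALUMINUM)
        assert 0.1 < lam < 2.0  # meters, order of the nuclear mfp

    def test_fragment_keeps_projectile_velocity(self):
        s = ParticleState(Z=26, A=56, E=1000.0, position=np.zeros(3),
                          direction=np.array([0, 0, 1.0]))
        rng = np.random.default_rng(2)
        for _ in range(20):
            secs = toy_nuclear_interaction(s, WATER, rng)
            frags = [p for p in secs if p.A > 1]
            for f in frags:
                assert f.E == pytest.approx(s.E, rel=1e-12)

    def test_deposit_stream_export(self, tmp_path):
        fx = build_fixture("free_space")
        s = proton(E=100.0, pos=(0, 0, -1.45), d=(0, 0, 1.0))
        dep, _ = propagate(PrimarySample(s, 0, 1.0), fx.geometry, fx.field,
                           TransportSettings(), np.random.default_rng(0),
                           record_all=True)
        from magshield.transport import deposits_to_csv
        path = tmp_path / "deposits.csv"
        deposits_to_csv(dep, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("x,y,z,dE_MeV")
        assert len(lines) == len(dep) + 1
        total = sum(float(l.split(",")[3]) for l in lines[1:])
        assert total == pytest.approx(100.0, rel=1e-3)

    def test_enabled_model_produces_secondaries(self):
        fx = build_fixture("free_space")
        st = TransportSettings(nuclear=True)
        rng = np.random.default_rng(8)
        kinds = set()
        for _ in range(50):
            s = ParticleState(Z=26, A=56, E=2000.0,
                              position=np.array([0.0, 0.0, -1.45]),
                              direction=np.array([0.0, 0.0, 1.0]))
            dep, _ = propagate(PrimarySample(s, 0, 1.0), fx.geometry,
                               fx.field, st, rng, record_all=True)
            kinds |= {d.lineage for d in dep}
        assert "secondary" in kinds
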