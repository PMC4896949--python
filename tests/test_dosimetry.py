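import numpy as np
import pytest

from magshield.dosimetry import (
    CHARGE_GROUPS,
    DoseTable,
    MissionConfig,
    Phantom,
    PhantomScore,
    dose_equivalent,
    epsilon,
    group_of,
)
from magshield.spectrum import GCRSpectrum


@pytest.fixture
def phantom():
    return Phantom(center=(0.0, 0.0, 0.0))


def single_bin_spectrum(f=1e-4 / 100.0, e0=100.0, e1=200.0):
    """One bin with f * dE = 1e-4 cm^-2 sr^-1 s^-1 by default."""
    e = np.array([e0, e1])
    return GCRSpectrum(energy=e, flux={1: np.array([f, f])})


class TestPhantomRegions:
    def test_masses(self, phantom):
        assert phantom.region_mass("body") == pytest.approx(81.4, abs=0.05)
        assert phantom.region_mass("skin") == pytest.approx(2.87, abs=0.01)
        assert phantom.region_mass("bfo") == pytest.approx(1.47, abs=0.01)

    def test_outer_two_mm_is_skin(self, phantom):
        assert phantom.region_of((0.1195, 0.0, 0.0)) == {"skin", "body"}

    def test_five_cm_depth_shell_is_bfo(self, phantom):
        assert phantom.region_of((0.069, 0.0, 0.0)) == {"bfo", "body"}

    def test_center_is_body_only(self, phantom):
        assert phantom.region_of((0.0, 0.0, 0.0)) == {"body"}

    def test_end_disks_are_skin(self, phantom):
        assert phantom.region_of((0.0, 0.0, 0.8995)) == {"skin", "body"}

    def test_bfo_excludes_axial_ends(self, phantom):
        # radially in the BFO shell but within 5 cm of the end: skin rules
        # do not apply, BFO does not either
        assert phantom.region_of((0.069, 0.0, 0.87)) == {"body"}

    def test_outside_is_empty(self, phantom):
        assert phantom.region_of((0.2, 0.0, 0.0)) == frozenset()

    def test_segment_fractions_sum(self, phantom):
        # diametral chord at mid-length: all body, 4 mm of skin
        fr = phantom.segment_region_fractions((-0.12, 0, 0), (0.12, 0, 0))
        assert fr["body"] == pytest.approx(1.0)
        assert fr["skin"] == pytest.approx(0.004 / 0.24, rel=0.1)
        assert fr["bfo"] == pytest.approx(0.004 / 0.24, rel=0.1)


class TestEpsilon:
    def test_unit_conversion(self):
        # 1 MeV at Q=1 in 81.4 kg
        assert epsilon(1.0, 5.0, 81.4) == pytest.approx(1.97e-15, rel=0.005)

    def test_quality_weighting(self):
        assert epsilon(1.0, 50.0, 81.4) / epsilon(1.0, 5.0, 81.4) == \
            pytest.approx(12.8, rel=1e-9)

    def test_inverse_mass_scaling(self):
        assert epsilon(1.0, 5.0, 40.7) == pytest.approx(
            2 * epsilon(1.0, 5.0, 81.4), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            epsilon(0.0, 5.0, 81.4)
        with pytest.raises(ValueError):
            epsilon(1.0, 5.0, 0.0)


class TestDoseAggregation:
    def test_zero_scores_zero_table(self):
        score = PhantomScore()
        score.record_primary(1, 0, 10)
        table = dose_equivalent(score, single_bin_spectrum(), 1.696e6,
                                MissionConfig(), n_phantoms=1)
        assert float(table.values.to_numpy().sum()) == 0.0

    def test_single_bin_closed_form(self):
        """d = s * A * f dE * t / N for one bin, one phantom."""
        score = PhantomScore()
        score.record_primary(1, 0, 1000)
        score.eps[(0, "body", 1, 0)] = 1e-15
        table = dose_equivalent(score, single_bin_spectrum(), 1.696e6,
                                MissionConfig(exposure_time=3.156e7),
                                n_phantoms=1)
        expected_sv = 1e-15 * 1.696e6 * 1e-4 * 3.156e7 / 1000.0
        assert expected_sv == pytest.approx(5.35e-9, rel=2e-3)
        assert table.values.loc["1", "body"] == pytest.approx(
            expected_sv * 100.0, rel=1e-9)

    def test_exposure_linearity(self):
        score = PhantomScore()
        score.record_primary(1, 0, 100)
        score.eps[(0, "body", 1, 0)] = 3e-14
        t1 = dose_equivalent(score, single_bin_spectrum(), 1.696e6,
                             MissionConfig(exposure_time=3.156e7),
                             n_phantoms=1)
        t2 = dose_equivalent(score, single_bin_spectrum(), 1.696e6,
                             MissionConfig(exposure_time=2 * 3.156e7),
                             n_phantoms=1)
        assert t2.values.to_numpy() == pytest.approx(
            2 * t1.values.to_numpy(), rel=1e-12)

    def test_total_row_is_group_sum(self):
        score = PhantomScore()
        for Z, j, val in ((1, 0, 1e-15), (2, 0, 2e-15), (26, 0, 5e-16)):
            score.record_primary(Z, j, 50)
            score.eps[(0, "body", Z, j)] = val
        e = np.array([100.0, 200.0])
        sp = GCRSpectrum(energy=e,
                         flux={z: np.array([1e-6, 1e-6]) for z in (1, 2, 26)})
        table = dose_equivalent(score, sp, 1e6, MissionConfig(), n_phantoms=1)
        groups = [g for g, _ in CHARGE_GROUPS]
        for region in ("skin", "bfo", "body"):
            assert table.values.loc["Total", region] == pytest.approx(
                sum(table.values.loc[g, region] for g in groups), rel=1e-12)

    def test_rms_uncertainty_across_phantoms(self):
        score = PhantomScore()
        score.record_primary(1, 0, 100)
        vals = [1e-15, 2e-15, 3e-15, 1e-15, 2e-15, 3e-15]
        for pid, v in enumerate(vals):
            score.eps[(pid, "body", 1, 0)] = v
        table = dose_equivalent(score, single_bin_spectrum(), 1e6,
                                MissionConfig(), n_phantoms=6)
        d = np.array(vals)
        rel_rms = np.sqrt(np.mean((d - d.mean()) ** 2)) / d.mean()
        cell = table.values.loc["1", "body"]
        err = table.errors.loc["1", "body"]
        assert err / cell == pytest.approx(rel_rms, rel=1e-9)

    def test_zero_count_with_flux_and_scores_raises(self):
        score = PhantomScore()
        score.eps[(0, "body", 1, 0)] = 1e-15  # scored but never counted
        with pytest.raises(ValueError, match="zero generated"):
            dose_equivalent(score, single_bin_spectrum(), 1e6,
                            MissionConfig(), n_phantoms=1)

    def test_missing_charge_in_spectrum_raises(self):
        score = PhantomScore()
        score.record_primary(26, 0, 10)
        score.eps[(0, "body", 26, 0)] = 1e-15
        with pytest.raises(ValueError, match="Z=26"):
            dose_equivalent(score, single_bin_spectrum(), 1e6,
                            MissionConfig(), n_phantoms=1)

    def test_group_of(self):
        assert group_of(1) == "1"
        assert group_of(7) == "3-10"
        assert group_of(28) == "21-28"
        with pytest.raises(ValueError):
            group_of(29)


class TestEstimatorConsistency:
    def test_per_bin_and_spectrum_sampled_agree(self):
        """The Eq.-6 (per-bin) and Eq.-7 (spectrum-sampled) estimators
        agree within Monte Carlo scatter on a free-space proton run."""
        from magshield.pipeline import RunConfig, run_pipeline
        doses = {}
        for scheme in ("per_bin", "spectrum_sampled"):
            cfg = RunConfig(fixture="free_space", z_list=(1,), n_per_z=12000,
                            scheme=scheme)
            doses[scheme] = run_pipeline(cfg, seed=17).table.total("body")
        spread = []
        for seed in (18, 19, 20):
            cfg = RunConfig(fixture="free_space", z_list=(1,), n_per_z=12000,
                            scheme="spectrum_sampled")
            spread.append(run_pipeline(cfg, seed=seed).table.total("body"))
        sigma = max(np.std(spread + [doses["spectrum_sampled"]]), 1e-6)
        assert abs(doses["per_bin"] - doses["spectrum_sampled"]) < \
            3.0 * sigma + 0.15 * doses["spectrum_sampled"]

    def test_short_range_ions_dose_skin_not_bfo(self):
        """Ions whose range is below the 5-cm BFO depth deposit in the
        skin shell and leave the BFO untouched — the mechanism behind the
        skin-dominated heavy-ion pattern in free space."""
        import numpy as np
        from magshield.fixtures import build_fixture
        from magshield.physics import ParticleState
        from magshield.source import PrimarySample
        from magshield.transport import TransportSettings, propagate
        fx = build_fixture("free_space")
        score = __import__("magshield.dosimetry",
                           fromlist=["PhantomScore"]).PhantomScore()
        rng = np.random.default_rng(0)
        # 40 MeV/n carbon: CSDA range ~ 5 mm in water
        for x in np.linspace(-0.1, 0.1, 9):
            s = ParticleState(Z=6, A=12, E=40.0,
                              position=np.array([x, -1.45, 0.0]),
                              direction=np.array([0.0, 1.0, 0.0]))
            propagate(PrimarySample(s, 0, 1.0), fx.geometry, fx.field,
                      TransportSettings(), rng, score=score)
        skin = sum(v for k, v in score.eps.items() if k[1] == "skin")
        bfo = sum(v for k, v in score.eps.items() if k[1] == "bfo")
        assert skin > 0
        assert bfo == 0.0

    def test_heavy_ion_skin_dose_exceeds_bfo(self):
        """Aggregated over Z >= 3, the free-space skin dose equivalent
        exceeds the BFO dose (short-range, high-LET stopping population
        plus the Q(L) falloff above L = 100 at depth)."""
        from magshield.pipeline import RunConfig, run_pipeline
        cfg = RunConfig(fixture="free_space", z_list=tuple(range(3, 29)),
                        n_per_z=900)
        res = run_pipeline(cfg, seed=31)
        assert res.table.total("skin") >= res.table.total("bfo")
        assert res.absorbed.total("skin") >= res.absorbed.total("bfo")

    def test_dose_equivalent_at_least_absorbed_for_low_let(self):
        """Q >= 1 wherever L < 100, so the dose equivalent bounds the
        absorbed dose for protons."""
        from magshield.pipeline import RunConfig, run_pipeline
        cfg = RunConfig(fixture="free_space", z_list=(1,), n_per_z=4000)
        res = run_pipeline(cfg, seed=21)
        for region in ("skin", "bfo", "body"):
            assert res.table.total(region) >= \
                res.absorbed.total(region) * (1.0 - 1e-9)
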