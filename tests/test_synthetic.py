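"""Synthetic acquisition generator: structure, additivity, determinism."""

import numpy as np
import pytest

from asapscreen.sir import integrate_peak
from asapscreen.spectra import CONE_VOLTAGES
from asapscreen.synthetic import (
    SampleDefinition,
    SimulationParams,
    generate_validation_set,
    simulate_acquisition,
    simulate_channel,
)

CLEAN = SimulationParams(noise_sigma=0.0)


class TestProfiles:
    def test_tpr_12v_base_peak(self, profiles):
        peaks = profiles["T Pr"].peaks_at(12)
        assert max(peaks, key=peaks.get) == 345

    def test_tren_40v_contains_ester_cleavage_pair(self, profiles):
        peaks = profiles["Tr En"].peaks_at(40)
        assert 271 in peaks and 253 in peaks

    def test_12v_precursor_dominates_for_all(self, registry, profiles):
        for record in registry:
            peaks = profiles[record.abbreviation].peaks_at(12)
            assert max(peaks, key=peaks.get) == record.protonated_mz

    def test_fragment_richness_monotone_in_voltage(self, registry, profiles):
        for record in registry:
            counts = [
                sum(1 for i in profiles[record.abbreviation].peaks_at(v).values() if i >= 5.0)
                for v in CONE_VOLTAGES
            ]
            assert counts == sorted(counts)

    def test_estradiol_esters_share_high_voltage_fragments(self, profiles):
        a = set(profiles["E2 V1"].peaks_at(40))
        b = set(profiles["E2 DiPr"].peaks_at(40))
        assert {279, 255, 159, 135, 109} <= (a & b)


class TestSimulateChannel:
    def test_single_constituent_proportional_to_profile(self, profiles):
        sample = SampleDefinition({"T Pr": 100.0}, matrix="none", seed=0)
        s = simulate_channel(sample, 40, profiles, CLEAN)
        expected = profiles["T Pr"].peaks_at(40)
        assert s.mz.astype(int).tolist() == sorted(expected)
        ratio = s.intensities / np.array([expected[m] for m in sorted(expected)])
        assert np.allclose(ratio, ratio[0])

    def test_mixture_is_union_of_profiles_pre_noise(self, profiles):
        sample = SampleDefinition({"T Pr": 100.0, "B Un": 100.0}, matrix="none", seed=0)
        s = simulate_channel(sample, 30, profiles, CLEAN)
        union = set(profiles["T Pr"].peaks_at(30)) | set(profiles["B Un"].peaks_at(30))
        assert set(s.mz.astype(int)) == union

    def test_mixture_additivity_pre_noise(self, profiles):
        a = simulate_channel(SampleDefinition({"T Pr": 100.0}, seed=0), 30, profiles, CLEAN)
        b = simulate_channel(SampleDefinition({"B Un": 100.0}, seed=0), 30, profiles, CLEAN)
        ab = simulate_channel(
            SampleDefinition({"T Pr": 100.0, "B Un": 100.0}, seed=0), 30, profiles, CLEAN
        )
        combined = {}
        for s in (a, b):
            for m, i in zip(s.mz, s.intensities):
                combined[m] = combined.get(m, 0.0) + i
        assert {m: i for m, i in zip(ab.mz, ab.intensities)} == pytest.approx(combined)

    def test_saturation_clips_base_peak(self, profiles):
        params = SimulationParams(noise_sigma=0.0, saturation_cap=1.0e6)
        sample = SampleDefinition({"T Pr": 5000.0}, matrix="none", seed=0)
        s = simulate_channel(sample, 12, profiles, params)
        assert s.intensities.max() == params.saturation_cap

    def test_unknown_constituent_rejected(self, profiles):
        with pytest.raises(KeyError, match="nope"):
            simulate_channel(SampleDefinition({"nope": 10.0}, seed=0), 12, profiles, CLEAN)

    def test_oil_matrix_adds_low_mass_biased_ions(self, profiles):
        blank = SampleDefinition({}, matrix="oil", seed=4)
        s = simulate_channel(blank, 12, profiles)
        assert len(s) > 20
        assert np.median(s.mz) < 350  # biased toward m/z 100-300


class TestSimulateAcquisition:
    def test_same_seed_reproduces_exactly(self, sim_params):
        sample = SampleDefinition({"T En": 100.0}, matrix="oil", seed=123)
        acq1, chr1 = simulate_acquisition(sample, sim_params)
        acq2, chr2 = simulate_acquisition(sample, sim_params)
        for v in CONE_VOLTAGES:
            assert acq1[v].mz.tolist() == acq2[v].mz.tolist()
            assert acq1[v].intensities.tolist() == acq2[v].intensities.tolist()
        for mz in chr1:
            assert chr1[mz].intensities.tolist() == chr2[mz].intensities.tolist()

    def test_blank_chronograms_are_baseline_only(self, sim_params):
        blank = SampleDefinition({}, matrix="oil", seed=2)
        _, chronos = simulate_acquisition(blank, sim_params)
        for c in chronos.values():
            assert c.intensities.max() < 3 * sim_params.baseline_level

    def test_chronograms_cover_all_17_monitored_mz(self, registry, sim_params):
        sample = SampleDefinition({"T Pr": 100.0}, matrix="none", seed=1)
        _, chronos = simulate_acquisition(sample, sim_params)
        assert set(chronos) == {r.sir_mz for r in registry}

    def test_present_compound_peak_has_12_to_13_points_at_10hz(self, sim_params):
        sample = SampleDefinition({"T Pr": 100.0}, matrix="none", seed=3)
        _, chronos = simulate_acquisition(sample, sim_params)
        pm = integrate_peak(chronos[345])
        assert 12 <= pm.n_points <= 13

    def test_2hz_sampling_gives_about_3_points(self):
        params = SimulationParams(sir_rate_hz=2.0)
        sample = SampleDefinition({"T Pr": 100.0}, matrix="none", seed=3)
        _, chronos = simulate_acquisition(sample, params)
        pm = integrate_peak(chronos[345])
        assert 2 <= pm.n_points <= 4


class TestValidationSet:
    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            generate_validation_set(n_samples=0)

    def test_requested_singles_have_one_constituent(self):
        data = generate_validation_set(n_samples=10, mixture_sizes=(1,), seed=5)
        assert len(data) == 10
        for sample, _ in data:
            assert len(sample.constituents) == 1

    def test_blanks_supported(self):
        data = generate_validation_set(n_samples=5, mixture_sizes=(0,), seed=5)
        assert all(not s.constituents for s, _ in data)

    def test_reproducible_under_seed(self):
        a = generate_validation_set(n_samples=4, seed=9)
        b = generate_validation_set(n_samples=4, seed=9)
        for (sa, (acqa, _)), (sb, (acqb, _)) in zip(a, b):
            assert sa == sb
            assert acqa[12].intensities.tolist() == acqb[12].intensities.tolist()
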