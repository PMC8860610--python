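"""Synthetic photon streams, burst tables and gel lanes: fidelity to the
statistical model the analysis assumes."""

import numpy as np
import pytest

from alexfret import (
    AA,
    DA,
    DD,
    BackgroundRates,
    BurstSearchParams,
    GelLane,
    GelSimConfig,
    SimConfig,
    SimSpecies,
    SimulationError,
    burst_table,
    classify_photons,
    dual_color_burst_search,
    fit_lane_gaussian,
    extract_lane_profile,
    lane_column_bounds,
    loss_of_fret,
    read_gel_tiff,
    select_bursts,
    simulate_burst_table,
    simulate_gel_image,
    simulate_lane_profile,
    simulate_photon_stream,
    two_state_mixture,
    write_gel_tiff,
)

NO_BACKGROUND = BackgroundRates(0, 0, 0, 0)


class TestSpeciesValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(species=[SimSpecies("a", 0.5, 0.2), SimSpecies("b", 0.4, 0.7)])

    def test_p_da_bounds(self):
        with pytest.raises(ValueError):
            SimSpecies("bad", 1.0, 1.5)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            SimSpecies("bad", 1.0, 0.5, dex_rate=-1)


class TestPhotonStreamSimulation:
    def test_identical_seed_gives_identical_stream(self):
        config = SimConfig(species=two_state_mixture(0.3), n_bursts=100, seed=42)
        a = simulate_photon_stream(config)
        b = simulate_photon_stream(config)
        assert np.array_equal(a.timestamps, b.timestamps)
        assert np.array_equal(a.detectors, b.detectors)

    def test_zero_p_da_puts_all_donor_window_photons_in_green(self):
        config = SimConfig(
            species=[SimSpecies("donor_only", 1.0, 0.0)],
            n_bursts=20,
            background=NO_BACKGROUND,
            seed=3,
        )
        labeled = classify_photons(simulate_photon_stream(config))
        assert np.count_nonzero(labeled.labels == DA) == 0
        assert np.count_nonzero(labeled.labels == DD) > 0

    def test_background_only_stream_yields_no_bursts(self):
        # DCBS thresholds sit far above any plausible background rate
        config = SimConfig(species=(), n_bursts=0, seed=5, total_duration_s=2.0)
        stream = simulate_photon_stream(config)
        assert len(stream) > 0  # background photons present
        bursts = dual_color_burst_search(classify_photons(stream), BurstSearchParams())
        assert bursts == []

    def test_species_fractions_conserved_in_truth_labels(self):
        config = SimConfig(species=two_state_mixture(0.2), n_bursts=4000, seed=9)
        _, truth = simulate_photon_stream(config, return_truth=True)
        frac = (truth["species"] == "low_fret").mean()
        bound = 3 * np.sqrt(0.2 * 0.8 / 4000)
        assert abs(frac - 0.2) < bound

    def test_burst_collision_beyond_retry_budget_raises(self):
        config = SimConfig(
            species=two_state_mixture(0.5),
            n_bursts=50,
            mean_burst_duration_ms=1000.0,  # 1 s bursts
            burst_rate_per_s=1000.0,  # arriving every ms: guaranteed pile-up
            max_retries=10,
            seed=1,
        )
        with pytest.raises(SimulationError, match="density"):
            simulate_photon_stream(config)

    def test_free_dna_regime_recovers_e_02_s_05(self):
        # p_da = 0.2 with matched DEX/AEX rates: burst means E* ~ 0.2, S ~ 0.5
        config = SimConfig(
            species=[SimSpecies("free_dna", 1.0, 0.2, dex_rate=100, aex_rate=100)],
            n_bursts=600,
            background=NO_BACKGROUND,
            seed=11,
        )
        stream = simulate_photon_stream(config)
        table = burst_table(dual_color_burst_search(classify_photons(stream)))
        assert len(table) > 200
        assert table["e_app"].mean() == pytest.approx(0.2, abs=0.02)
        assert table["s"].mean() == pytest.approx(0.5, abs=0.02)


class TestBurstTableFastPath:
    def test_identical_seed_gives_identical_table(self):
        config = SimConfig(species=two_state_mixture(0.3), n_bursts=500, seed=7)
        a = simulate_burst_table(config)
        b = simulate_burst_table(config)
        assert a.equals(b)

    def test_mean_e_converges_to_p_da(self):
        config = SimConfig(
            species=[SimSpecies("mid", 1.0, 0.5, dex_rate=2000, aex_rate=2000)],
            n_bursts=2000,
            seed=2,
        )
        table = simulate_burst_table(config)
        assert table["e_app"].mean() == pytest.approx(0.5, abs=0.01)

    def test_acceptor_absent_species_has_s_of_one(self):
        config = SimConfig(
            species=[SimSpecies("donor_only", 1.0, 0.1, aex_rate=0.0)],
            n_bursts=300,
            seed=4,
        )
        table = simulate_burst_table(config)
        assert (table["s"] == 1.0).all()

    def test_mixture_weight_recovered_by_threshold_split(self):
        config = SimConfig(species=two_state_mixture(0.3), n_bursts=8000, seed=6)
        table = select_bursts(simulate_burst_table(config), min_size=30)
        est = loss_of_fret(table)
        true_frac = 100 * (table["species"] == "low_fret").mean()
        bound = 3 * np.sqrt(0.3 * 0.7 / len(table)) * 100 + 1.0  # labels + shot noise
        assert abs(est - true_frac) < bound

    def test_hidden_labels_do_not_affect_statistics(self):
        config = SimConfig(species=two_state_mixture(0.3), n_bursts=500, seed=7)
        table = simulate_burst_table(config)
        assert loss_of_fret(table) == loss_of_fret(table.drop(columns="species"))


class TestGelSimulation:
    config = GelSimConfig(
        lanes=(
            GelLane(band_center=120.0, band_sigma=15.0, amplitude=1000.0, baseline=50.0),
            GelLane(band_center=300.0, band_sigma=20.0, amplitude=800.0, baseline=40.0),
        ),
        profile_length=512,
        noise_sd=0.0,
        seed=0,
    )

    def test_noiseless_profile_peaks_at_band_center(self):
        profile = simulate_lane_profile(self.config, 0)
        assert profile.positions[np.argmax(profile.intensities)] == 120.0

    def test_noiseless_fit_recovers_center_exactly(self):
        fit = fit_lane_gaussian(simulate_lane_profile(self.config, 0))
        assert fit.converged
        assert fit.center == pytest.approx(120.0, abs=1e-6)
        assert fit.sigma == pytest.approx(15.0, abs=1e-6)

    def test_zero_amplitude_lane_flags_degenerate_fit(self):
        config = GelSimConfig(
            lanes=(GelLane(100.0, 10.0, 0.0, 50.0),), profile_length=256, seed=0
        )
        fit = fit_lane_gaussian(simulate_lane_profile(config, 0))
        assert not fit.converged

    def test_image_lane_extraction_reproduces_profile_exactly(self):
        image = simulate_gel_image(self.config)
        for i, (lo, hi) in enumerate(lane_column_bounds(2)):
            extracted = extract_lane_profile(image, lo, hi)
            expected = simulate_lane_profile(self.config, i)
            np.testing.assert_array_equal(extracted.intensities, expected.intensities)

    def test_two_lane_fitted_centers_ordered_as_configured(self):
        noisy = GelSimConfig(lanes=self.config.lanes, profile_length=512, noise_sd=5.0, seed=3)
        image = simulate_gel_image(noisy)
        centers = [
            fit_lane_gaussian(extract_lane_profile(image, lo, hi)).center
            for lo, hi in lane_column_bounds(2)
        ]
        assert centers[0] < centers[1]

    def test_empty_lane_list_gives_uniform_image(self):
        image = simulate_gel_image(GelSimConfig(lanes=(), profile_length=64, seed=0))
        assert np.all(image == image[0, 0])

    def test_intensity_overflow_raises(self):
        config = GelSimConfig(
            lanes=(GelLane(100.0, 10.0, 7e6, 0.0),), profile_length=256, seed=0
        )
        with pytest.raises(SimulationError, match="16-bit"):
            simulate_gel_image(config)

    def test_band_center_outside_profile_rejected(self):
        with pytest.raises(ValueError):
            GelSimConfig(lanes=(GelLane(600.0, 10.0, 100.0),), profile_length=512)

    def test_tiff_round_trip(self, tmp_path):
        image = simulate_gel_image(self.config)
        path = tmp_path / "gel.tif"
        write_gel_tiff(image, path)
        back = read_gel_tiff(path)
        assert back.shape == image.shape
        np.testing.assert_allclose(back, image, atol=0.5)  # 16-bit rounding
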