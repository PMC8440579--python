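"""Generator contracts: dwell models, trace/movie/ring rendering, titration."""

import numpy as np
import pytest
from scipy import stats

from smlife import simkit
from smlife.simkit import (
    AcquisitionParams,
    DwellModel,
    PhotophysicsParams,
    apply_photobleaching,
    render_movie,
    render_ring_cells,
    render_trace,
    simulate_dwell_times,
    simulate_titration,
)


class TestDwellTimes:
    def test_treadmill_dwell_is_length_over_speed(self):
        model = DwellModel(mode="treadmill", filament_length_um=2.0, treadmill_speed_um_s=0.5)
        assert simulate_dwell_times(model, 3, seed=0).tolist() == [4.0, 4.0, 4.0]

    def test_exponential_mean_matches_tau(self):
        d = simulate_dwell_times(DwellModel(tau_s=5.0), 100_000, seed=42)
        assert abs(d.mean() - 5.0) < 0.05

    def test_same_seed_same_samples(self):
        model = DwellModel(tau_s=3.0)
        a = simulate_dwell_times(model, 1000, seed=9)
        b = simulate_dwell_times(model, 1000, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_exponential_distribution_ks(self):
        d = simulate_dwell_times(DwellModel(tau_s=5.0), 10_000, seed=3)
        assert stats.kstest(d, "expon", args=(0, 5.0)).pvalue > 0.01

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mode": "exponential", "tau_s": -1.0},
            {"mode": "treadmill", "filament_length_um": -2.0, "treadmill_speed_um_s": 0.5},
            {"mode": "treadmill", "filament_length_um": 2.0, "treadmill_speed_um_s": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DwellModel(**kwargs)

    def test_photobleach_truncation_scales_with_frame_interval(self):
        dwells = np.full(20_000, 50.0)  # much longer than bleaching
        fast = apply_photobleaching(dwells, 0.2, 0.5, seed=1)
        slow = apply_photobleaching(dwells, 0.2, 1.0, seed=1)
        # same geometric exposure counts, so lifetimes scale with interval
        assert abs(fast.mean() * 2 - slow.mean()) < 1e-9
        assert abs(fast.mean() - 0.5 / 0.2) < 0.1


class TestRenderTrace:
    def test_step_function(self, noise_free, acq_halfsec):
        values, truth = render_trace(5.0, 5.0, acq_halfsec, noise_free, seed=0)
        expected = np.zeros(60)
        expected[10:20] = 800.0
        np.testing.assert_allclose(values, expected)
        assert truth["unbind_s"] == 10.0

    def test_partial_frame_overlap_scales_amplitude(self, noise_free, acq_halfsec):
        values, _ = render_trace(5.25, 5.0, acq_halfsec, noise_free, seed=0)
        assert values[10] == pytest.approx(400.0)  # half-frame overlap
        np.testing.assert_allclose(values[11:20], 800.0)
        assert values[20] == pytest.approx(400.0)

    def test_immediate_bleach_leaves_at_most_one_bright_frame(self, acq_halfsec):
        phot = PhotophysicsParams(
            spot_amplitude_counts=800,
            background_counts=0,
            read_noise_sd_counts=0,
            shot_noise=False,
            bleach_rate_per_exposure=1.0,
            amplitude_cv=0.0,
        )
        values, truth = render_trace(5.0, 20.0, acq_halfsec, phot, seed=0)
        assert np.count_nonzero(values) <= 1
        assert truth["bleach_frame"] == 10

    def test_shot_noise_variance_matches_poisson(self):
        acq = AcquisitionParams(n_frames=10_000)
        phot = PhotophysicsParams(
            spot_amplitude_counts=800,
            background_counts=100,
            read_noise_sd_counts=0,
            shot_noise=True,
            amplitude_cv=0.0,
        )
        values, _ = render_trace(0.0, acq.duration_s, acq, phot, seed=5)
        # Poisson(signal + background) predicts variance 900 on bound frames
        assert values.var() == pytest.approx(900.0, rel=0.1)
        assert values.mean() == pytest.approx(800.0, abs=3 * 30 / 100)


class TestRenderMovie:
    def test_centroid_oracle_recovers_position(self, noise_free):
        acq = AcquisitionParams(n_frames=20)
        movie, mask, man = render_movie(
            1, 1, DwellModel(tau_s=1e6), acq, noise_free, image_shape=(64, 64), seed=4
        )
        m = man.molecules[0]
        first = int(np.ceil(m["bind_s"] / acq.frame_interval_s))
        for frame in movie[first + 1 :]:
            total = frame.sum()
            rr, cc = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
            com_r = (rr * frame).sum() / total
            com_c = (cc * frame).sum() / total
            assert abs(com_r - m["row"]) < 0.25
            assert abs(com_c - m["col"]) < 0.25

    def test_manifest_counts_and_mask_cover_positions(self, small_movie):
        _, mask, man, _ = small_movie
        assert len(man.molecules) == 8 * 3
        for m in man.molecules:
            assert mask[int(round(m["row"])), int(round(m["col"]))] == m["cell_id"]

    def test_zero_molecules_gives_pure_background(self, noise_free):
        acq = AcquisitionParams(n_frames=5)
        movie, _, man = render_movie(
            2, 0, DwellModel(tau_s=5.0), acq, noise_free, image_shape=(80, 80), seed=0
        )
        np.testing.assert_array_equal(movie, 0.0)
        assert man.molecules == []

    def test_zero_noise_render_bitwise_reproducible(self, noise_free):
        acq = AcquisitionParams(n_frames=10)
        a = render_movie(2, 2, DwellModel(tau_s=4.0), acq, noise_free, (100, 100), seed=12)
        b = render_movie(2, 2, DwellModel(tau_s=4.0), acq, noise_free, (100, 100), seed=12)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert a[2].to_json() == b[2].to_json()

    def test_infeasible_packing_raises(self, noise_free):
        acq = AcquisitionParams(n_frames=2)
        with pytest.raises(ValueError):
            render_movie(50, 1, DwellModel(tau_s=5.0), acq, noise_free, (60, 60), seed=0)

    def test_manifest_round_trips_through_json(self, small_movie, tmp_path):
        _, _, man, _ = small_movie
        path = tmp_path / "manifest.json"
        man.to_json(path)
        again = simkit.GroundTruthManifest.from_json(path)
        assert again == man


class TestRenderRingCells:
    def test_midcell_ring_peaks_at_midcell(self, noise_free):
        acq = AcquisitionParams(n_frames=1)
        img, mask, mids, man = render_ring_cells(
            1, 4.0, 1, 0.2, acq, noise_free, (80, 80), seed=0, ring_position_frac=0.5
        )
        cell = man.cells[0]
        cols = np.arange(img.shape[1])
        in_cell_cols = (mask > 0).any(axis=0)
        profile = img.sum(axis=0)
        peak_col = cols[np.argmax(profile * in_cell_cols)]
        mid_col = cell["col_start"] + 0.5 * cell["length_um"] / acq.pixel_size_um
        assert abs(peak_col - mid_col) <= 1.0

    def test_no_rings_gives_flat_cell_interior(self, noise_free):
        acq = AcquisitionParams(n_frames=1)
        img, mask, _, _ = render_ring_cells(2, 4.0, 0, 0.2, acq, noise_free, (90, 90), seed=1)
        inside = img[mask > 0]
        assert np.allclose(inside, inside[0])

    def test_manifest_fwhm_is_gaussian_identity(self, noise_free):
        acq = AcquisitionParams(n_frames=1)
        _, _, _, man = render_ring_cells(
            3, 4.0, 1, 0.2, acq, noise_free, (120, 120), seed=2
        )
        for cell in man.cells:
            assert cell["ring_fwhm_um"] == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 0.2)
            for pos in cell["ring_positions_um"]:
                assert 0 < pos < cell["length_um"]


class TestTitration:
    def test_midpoint_arithmetic(self):
        table, _ = simulate_titration(1.0, 100.0, 1.0, 1.0, [1.0], 1, 0.0, seed=0)
        assert table["response"].iloc[0] == pytest.approx(50.5)

    def test_zero_dose_returns_leak(self):
        table, _ = simulate_titration(1.0, 100.0, 1.0, 1.0, [0.0], 1, 0.0, seed=0)
        assert table["response"].iloc[0] == pytest.approx(1.0)

    def test_multiplicative_noise_is_mean_corrected(self):
        table, _ = simulate_titration(1.0, 100.0, 1.0, 1.0, [100.0], 4000, 0.2, seed=8)
        # lognormal noise with CV 0.2 and mean 1: response mean ~ model value
        model_value = 1.0 + 99.0 * 100.0 / 101.0
        assert table["response"].mean() == pytest.approx(model_value, rel=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_titration(1.0, 100.0, -1.0, 1.0, [0, 1, 2, 3], 1, 0.0, 0)
        with pytest.raises(ValueError):
            simulate_titration(1.0, 100.0, 1.0, 0.0, [0, 1, 2, 3], 1, 0.0, 0)
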