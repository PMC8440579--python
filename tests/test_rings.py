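"""Midline profiles, ring calls, widths, frequency and cell lengths."""

import numpy as np
import pandas as pd
import pytest

from smlife import simkit
from smlife.rings import (
    FWHM_FACTOR,
    MidlineProfile,
    detect_rings,
    measure_cell_lengths,
    midline_profile,
    principal_axis_midline,
    ring_frequency,
    ring_width_average,
    smooth_profile,
)


@pytest.fixture(scope="module")
def ring_scene(noise_free):
    acq = simkit.AcquisitionParams(n_frames=1)
    img, mask, mids, man = simkit.render_ring_cells(
        4, 4.0, 1, 0.2, acq, noise_free, (200, 200), seed=5, ring_position_frac=0.5
    )
    return img, mask, mids, man, acq


def gaussian_profile(sigma_um=0.2, length_um=4.0, step_um=0.1, amp=600.0, center_um=2.0):
    x = np.arange(0, length_um + step_um / 2, step_um)
    return MidlineProfile(1, x, amp * np.exp(-((x - center_um) ** 2) / (2 * sigma_um**2)))


class TestCellLengths:
    def test_rod_length_recovered(self):
        mask = np.zeros((60, 80), dtype=int)
        mask[20:28, 10:50] = 1  # 40 x 8 px rod
        out = measure_cell_lengths(mask, 0.1)
        assert out["length_um"].iloc[0] == pytest.approx(4.0, abs=0.2)
        assert not out["excluded_edge"].iloc[0]

    def test_border_touching_cell_flagged(self):
        mask = np.zeros((60, 80), dtype=int)
        mask[0:8, 10:50] = 1
        assert measure_cell_lengths(mask)["excluded_edge"].iloc[0]

    def test_empty_mask_empty_result(self):
        assert len(measure_cell_lengths(np.zeros((10, 10), dtype=int))) == 0

    def test_diagonal_rod_measured_along_axis(self):
        mask = np.zeros((80, 80), dtype=int)
        for i in range(40):
            mask[20 + i, 20 + i] = 1
        out = measure_cell_lengths(mask, 0.1)
        assert out["length_um"].iloc[0] == pytest.approx(39 * np.sqrt(2) * 0.1 + 0.1, abs=0.15)


class TestMidlineProfile:
    def test_uniform_cell_gives_flat_profile(self, ring_scene):
        img, mask, mids, man, acq = ring_scene
        flat = np.where(mask > 0, 77.0, 0.0)
        cell = man.cells[0]
        p = midline_profile(flat, mask, mids[cell["label"]], cell["label"])
        np.testing.assert_allclose(p.intensity, 77.0, atol=1e-9)

    def test_ridge_peak_at_midcell(self, ring_scene):
        img, mask, mids, man, _ = ring_scene
        cell = man.cells[0]
        p = midline_profile(img, mask, mids[cell["label"]], cell["label"])
        peak_um = p.arclength_um[np.argmax(p.intensity)]
        assert abs(peak_um - cell["ring_positions_um"][0]) <= 2 * p.step_um

    def test_profile_linear_in_image(self, ring_scene):
        img, mask, mids, man, _ = ring_scene
        cell = man.cells[0]
        a = midline_profile(img, mask, mids[cell["label"]], cell["label"]).intensity
        b = midline_profile(2.0 * img, mask, mids[cell["label"]], cell["label"]).intensity
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-12)

    def test_midline_outside_mask_rejected(self, ring_scene):
        img, mask, _, man, _ = ring_scene
        bad = np.array([[1.0, 1.0], [1.0, 30.0]])  # background corridor
        with pytest.raises(ValueError):
            midline_profile(img, mask, bad, man.cells[0]["label"])

    def test_principal_axis_midline_spans_cell(self, ring_scene):
        _, mask, _, man, _ = ring_scene
        cell = man.cells[0]
        line = principal_axis_midline(mask, cell["label"])
        span_um = np.hypot(*(line[-1] - line[0])) * 0.1
        assert span_um == pytest.approx(cell["length_um"], abs=0.3)


class TestDetectRings:
    def test_flat_profile_no_rings(self):
        p = MidlineProfile(1, np.arange(0, 4, 0.1), np.full(40, 10.0))
        assert detect_rings(p) == []

    def test_gaussian_ridge_fwhm_identity(self):
        calls = detect_rings(gaussian_profile(0.2), min_prominence=50)
        assert len(calls) == 1
        assert calls[0].fwhm_um == pytest.approx(FWHM_FACTOR * 0.2, rel=0.05)
        assert calls[0].position_um == pytest.approx(2.0, abs=0.1)

    def test_two_ridges_resolved(self):
        x = np.arange(0, 6, 0.1)
        y = 600 * np.exp(-((x - 1.5) ** 2) / (2 * 0.04)) + 600 * np.exp(
            -((x - 3.5) ** 2) / (2 * 0.04)
        )
        calls = detect_rings(MidlineProfile(1, x, y), min_prominence=50)
        assert len(calls) == 2
        assert calls[0].position_um == pytest.approx(1.5, abs=0.1)
        assert calls[1].position_um == pytest.approx(3.5, abs=0.1)

    def test_manifest_recall_and_precision_zero_noise(self, ring_scene):
        img, mask, mids, man, acq = ring_scene
        n_true = n_called = n_matched = 0
        for cell in man.cells:
            p = midline_profile(img, mask, mids[cell["label"]], cell["label"])
            calls = detect_rings(p, min_prominence=50)
            n_true += len(cell["ring_positions_um"])
            n_called += len(calls)
            for c in calls:
                if any(abs(c.position_um - t) < 0.3 for t in cell["ring_positions_um"]):
                    n_matched += 1
        assert n_matched == n_true == n_called  # recall = precision = 1.0


class TestRingWidthAverage:
    def test_identical_rings_average_to_single_width(self):
        p = gaussian_profile(0.2)
        calls = detect_rings(p, min_prominence=50)
        out = ring_width_average({1: smooth_profile(p)}, calls)
        assert out["averaged_fwhm_um"] == pytest.approx(calls[0].fwhm_um, rel=0.07)

    def test_mixed_widths_average_between_extremes(self):
        pa, pb = gaussian_profile(0.15), gaussian_profile(0.25)
        pb.cell_id = 2
        ca = detect_rings(pa, min_prominence=50)
        cb = detect_rings(pb, min_prominence=50)
        out = ring_width_average(
            {1: smooth_profile(pa), 2: smooth_profile(pb)}, ca + cb
        )
        assert ca[0].fwhm_um < out["averaged_fwhm_um"] < cb[0].fwhm_um

    def test_window_past_profile_skipped(self):
        p = gaussian_profile(0.2, center_um=0.3)  # ring near the pole
        calls = detect_rings(p, min_prominence=50)
        with pytest.raises(ValueError):
            ring_width_average({1: smooth_profile(p)}, calls)


class TestRingFrequency:
    def _lengths(self, n, length=4.0):
        return pd.DataFrame(
            {"cell_id": range(1, n + 1), "length_um": [length] * n, "excluded_edge": False}
        )

    def test_one_ring_per_four_micron_cell(self):
        from smlife.rings import RingCall

        calls = [RingCall(i, 2.0, 100.0, 0.4) for i in range(1, 21)]
        out = ring_frequency(calls, self._lengths(20))
        assert out["frequency_per_um"] == pytest.approx(0.25)

    def test_zero_rings_zero_frequency(self):
        out = ring_frequency([], self._lengths(5))
        assert out["frequency_per_um"] == 0.0

    def test_ringless_cells_count_in_denominator(self):
        from smlife.rings import RingCall

        out = ring_frequency([RingCall(1, 2.0, 100.0, 0.4)], self._lengths(2))
        assert out["frequency_per_um"] == pytest.approx(1 / 8.0)

    def test_invariant_to_intensity_scaling_and_relabeling(self, ring_scene):
        img, mask, mids, man, _ = ring_scene
        lengths = measure_cell_lengths(mask)
        kept = lengths[~lengths["excluded_edge"]]

        def freq(image, mapping=None):
            calls = []
            for cell in man.cells:
                label = cell["label"]
                p = midline_profile(image, mask, mids[label], label)
                for c in detect_rings(p, min_prominence=20):
                    calls.append(c)
            return ring_frequency(calls, kept)["frequency_per_um"]

        assert freq(img) == pytest.approx(freq(img * 3.0))
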