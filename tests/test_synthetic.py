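"""The simulator must honor its own ground truth exactly."""

import dataclasses

import numpy as np
import pytest

from golgikin.exceptions import ConfigurationError, InvalidParameterError
from golgikin.synthetic import (
    MarkerSpec,
    SimConfig,
    marker_pulse,
    noise_free,
    simulate_cell_image,
    simulate_coloc_snapshot,
    simulate_maturation_movie,
)


class TestMarkerPulse:
    def test_peak_value(self):
        assert marker_pulse(60.0, 60.0, 5.0, 100.0) == pytest.approx(100.0)

    @pytest.mark.parametrize("sign", [-1, 1])
    def test_one_sigma_value(self, sign):
        # at peak +/- width the Gaussian pulse is amplitude * e^(-1/2)
        val = marker_pulse(60.0 + sign * 8.0, 60.0, 8.0, 100.0)
        assert val == pytest.approx(100.0 * np.exp(-0.5))

    def test_sampled_argmax_at_peak(self):
        t = np.arange(0.0, 121.0, 2.0)
        vals = marker_pulse(t, 60.0, 10.0, 100.0)
        assert t[np.argmax(vals)] == 60.0

    def test_symmetric_and_positive(self):
        t = np.linspace(0, 120, 61)
        v = marker_pulse(t, 60.0, 7.0, 50.0)
        assert np.all(v > 0)
        assert np.allclose(v, v[::-1])

    def test_invalid_width(self):
        with pytest.raises(InvalidParameterError):
            marker_pulse(0.0, 0.0, 0.0, 100.0)


class TestMaturationMovie:
    def test_determinism(self):
        cfg = SimConfig(image_shape=(96, 96), n_puncta=3, seed=1)
        markers = [MarkerSpec("a", 0.0, 10.0), MarkerSpec("b", 4.0, 10.0)]
        m1, g1 = simulate_maturation_movie(cfg, markers)
        m2, g2 = simulate_maturation_movie(cfg, markers)
        assert np.array_equal(m1.data, m2.data)
        assert g1.puncta.equals(g2.puncta)

    def test_zero_offset_channels_peak_together(self, clean_pair_movie):
        movie, gt = clean_pair_movie
        bg = 0.0  # noise-free config has illumination off; background is uniform
        for _, p in gt.puncta.iterrows():
            r, c = int(round(p.row)), int(round(p.col))
            patch = movie.data[:, :, r - 3 : r + 4, c - 3 : c + 4].sum(axis=(2, 3))
            assert np.argmax(patch[:, 0]) == np.argmax(patch[:, 1])

    def test_designed_offset_in_frames(self):
        cfg = noise_free(SimConfig(image_shape=(96, 96), n_puncta=1, seed=5))
        markers = [MarkerSpec("a", 0.0, 10.0), MarkerSpec("b", 10.0, 10.0)]
        movie, gt = simulate_maturation_movie(cfg, markers)
        r = int(round(gt.puncta.row[0]))
        c = int(round(gt.puncta.col[0]))
        patch = movie.data[:, :, r - 3 : r + 4, c - 3 : c + 4].sum(axis=(2, 3))
        assert np.argmax(patch[:, 1]) - np.argmax(patch[:, 0]) == 5

    def test_ground_truth_peak_times_match_offsets(self):
        cfg = SimConfig(n_puncta=4, seed=2)
        markers = [MarkerSpec("a", 0.0, 10.0), MarkerSpec("b", 12.0, 10.0)]
        _, gt = simulate_maturation_movie(cfg, markers)
        diff = gt.puncta["peak_time_b"] - gt.puncta["peak_time_a"]
        assert np.allclose(diff, 12.0)

    def test_spot_flux_conservation(self):
        # integrated spot intensity = pulse value * 2*pi*sigma^2 within 1%
        cfg = noise_free(
            SimConfig(image_shape=(96, 96), n_puncta=1, seed=3, background_level=0.0)
        )
        markers = [MarkerSpec("a", 0.0, 10.0, amplitude=600.0), MarkerSpec("b", 0.0, 10.0)]
        movie, gt = simulate_maturation_movie(cfg, markers)
        t_peak = gt.puncta["peak_time_a"][0]
        frame_idx = int(round(t_peak / cfg.frame_interval))
        pulse = marker_pulse(movie.times[frame_idx], t_peak, 10.0, 600.0)
        expected = pulse * 2 * np.pi * cfg.psf_sigma**2
        assert movie.data[frame_idx, 0].sum() == pytest.approx(expected, rel=0.01)

    def test_pulse_not_fitting_names_marker(self):
        cfg = SimConfig(n_puncta=1, duration=30.0, seed=0)
        markers = [MarkerSpec("ok", 0.0, 5.0), MarkerSpec("late", 25.0, 5.0)]
        with pytest.raises(ConfigurationError, match="late"):
            simulate_maturation_movie(cfg, markers)

    def test_requires_reference_marker(self):
        cfg = SimConfig(n_puncta=1, seed=0)
        markers = [MarkerSpec("a", 5.0, 10.0), MarkerSpec("b", 10.0, 10.0)]
        with pytest.raises(ConfigurationError, match="reference"):
            simulate_maturation_movie(cfg, markers)

    def test_hot_pixels_recorded_and_only_difference(self):
        cfg = dataclasses.replace(
            noise_free(SimConfig(image_shape=(96, 96), n_puncta=2, seed=9)),
            hot_pixel_rate=1e-3,
        )
        markers = [MarkerSpec("a", 0.0, 10.0), MarkerSpec("b", 0.0, 10.0)]
        hot_movie, gt = simulate_maturation_movie(cfg, markers)
        ref_movie, _ = simulate_maturation_movie(
            dataclasses.replace(cfg, hot_pixel_rate=0.0), markers
        )
        diff = hot_movie.data != ref_movie.data
        recorded = set(map(tuple, gt.hot_pixels[["frame", "channel", "row", "col"]].to_numpy()))
        assert set(map(tuple, np.argwhere(diff))) <= recorded


class TestColocSnapshot:
    def test_coincident_centroids_match(self, clean_snapshot):
        _, gt = clean_snapshot
        green = gt.puncta.query("channel == 'green'").set_index("punctum_id")
        red = gt.puncta.query("channel == 'red'").set_index("punctum_id")
        for _, pair in gt.coloc_pairs.iterrows():
            g = green.loc[pair.green_id]
            r = red.loc[int(pair.red_id)]
            assert (g.row, g.col) == (r.row, r.col)

    def test_green_only_labeled_zero_overlap(self):
        cfg = SimConfig(image_shape=(128, 128), seed=4)
        _, gt = simulate_coloc_snapshot(cfg, 0, 10, 0)
        assert (gt.coloc_pairs["overlap_fraction"] == 0.0).all()
        assert gt.coloc_pairs["red_id"].isna().all()

    def test_ground_truth_deterministic(self):
        cfg = SimConfig(image_shape=(256, 256), seed=11)
        img1, gt1 = simulate_coloc_snapshot(cfg, 30, 10, 10)
        img2, gt2 = simulate_coloc_snapshot(cfg, 30, 10, 10)
        assert np.array_equal(img1, img2)
        assert gt1.puncta.equals(gt2.puncta)
        assert gt1.coloc_pairs.equals(gt2.coloc_pairs)


class TestCellImage:
    def _clean_cfg(self, seed=6):
        return noise_free(
            SimConfig(image_shape=(160, 160), seed=seed, background_level=0.0)
        )

    @pytest.mark.parametrize(
        "fraction,inside,outside",
        [(0.0, 0.0, 1.0), (1.0, 1.0, 0.0)],
    )
    def test_extreme_fractions(self, fraction, inside, outside):
        img, cells, vacs, _ = simulate_cell_image(self._clean_cfg(), 3, fraction)
        total = img[cells > 0].sum()
        assert img[vacs > 0].sum() == pytest.approx(inside * total)

    def test_designed_fraction_recovered_by_summation(self):
        img, cells, vacs, _ = simulate_cell_image(self._clean_cfg(), 4, 0.4)
        for cid in range(1, 5):
            ratio = img[vacs == cid].sum() / img[cells == cid].sum()
            assert ratio == pytest.approx(0.400, abs=5e-4)

    def test_vacuole_must_fit(self):
        with pytest.raises(ConfigurationError):
            simulate_cell_image(self._clean_cfg(), 1, 0.4, vacuole_radius_fraction=1.2)

    def test_invalid_fraction(self):
        with pytest.raises(ConfigurationError):
            simulate_cell_image(self._clean_cfg(), 1, 1.5)
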