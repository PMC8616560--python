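"""Tracking, trace normalization, peak timing and ordering — each checked
against constructions with known answers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from golgikin.exceptions import (
    DegenerateTraceError,
    InsufficientDataError,
    InvalidParameterError,
)
from golgikin.kinetics import (
    NormalizedTrace,
    PeakToPeakResult,
    Track,
    average_traces,
    extract_trace,
    marker_order,
    normalize_trace,
    peak_time,
    peak_to_peak,
    select_analyzable_tracks,
    summarize_peak_to_peak,
    track_puncta,
)
from golgikin.pipeline import analyze_movie
from golgikin.synthetic import MarkerSpec, SimConfig, noise_free, simulate_maturation_movie


def _pulse_track(track_id=0, peak_frame=30, width_s=10.0, offset_s=0.0, n_frames=61,
                 first=1, last=None, dt=2.0):
    """Synthetic track carrying Gaussian pulses (channel 1 offset by offset_s)."""
    last = (n_frames - 2) if last is None else last
    frames = list(range(first, last + 1))
    t = np.array(frames) * dt
    g = np.exp(-((t - peak_frame * dt) ** 2) / (2 * width_s**2))
    r = np.exp(-((t - peak_frame * dt - offset_s) ** 2) / (2 * width_s**2))
    return Track(
        track_id=track_id,
        frames=frames,
        positions=np.tile([20.0, 20.0], (len(frames), 1)),
        frame_interval=dt,
        channel_names=["green", "red"],
        raw_trace=np.stack([g, r]) * 1000.0,
    )


class TestTracking:
    def test_single_constant_spot_yields_one_full_track(self, constant_spot_movie):
        tracks = track_puncta(constant_spot_movie)
        assert len(tracks) == 1
        assert tracks[0].frames == list(range(61))

    def test_two_puncta_no_identity_swap(self):
        cfg = noise_free(
            SimConfig(image_shape=(96, 96), n_puncta=2, seed=17, jitter_sigma=0.3,
                      min_separation=30.0)
        )
        markers = [MarkerSpec("g", 0.0, 10.0), MarkerSpec("r", 0.0, 10.0)]
        movie, gt = simulate_maturation_movie(cfg, markers)
        tracks = track_puncta(movie)
        long_tracks = [t for t in tracks if t.n_frames >= 5]
        assert len(long_tracks) == 2
        truth = gt.puncta[["row", "col"]].to_numpy()
        for tr in long_tracks:
            dists = np.linalg.norm(truth - tr.positions.mean(axis=0), axis=1)
            # every position on the track stays with one ground-truth punctum
            owner = truth[np.argmin(dists)]
            assert np.all(np.linalg.norm(tr.positions - owner, axis=1) < 5.0)

    def test_track_support_matches_pulse_lifetime(self):
        # one spot pulsing at t=60 s on a noisy background: detection (and
        # hence the track) must start after frame 0 and die before the end
        from golgikin.synthetic import MovieStack, marker_pulse

        rng = np.random.default_rng(19)
        yy, xx = np.mgrid[0:96, 0:96]
        kernel = np.exp(-((yy - 48.0) ** 2 + (xx - 50.0) ** 2) / (2 * 1.5**2))
        frames = []
        for t in np.arange(0, 121, 2.0):
            scene = 100.0 + marker_pulse(t, 60.0, 10.0, 600.0) * kernel
            frame = rng.poisson(scene).astype(float)
            frames.append(np.stack([frame, frame]))
        movie = MovieStack(np.array(frames), 2.0, ["g", "r"])
        tracks = [t for t in track_puncta(movie) if t.n_frames >= 5]
        assert len(tracks) == 1
        assert tracks[0].frames[0] > 0
        assert tracks[0].frames[-1] < movie.n_frames - 1
        assert tracks[0].frames[0] * 2.0 < 60.0 < tracks[0].frames[-1] * 2.0


class TestExtractTrace:
    def test_zero_movie_region_gives_zero_trace(self, constant_spot_movie):
        tr = Track(0, [5, 6, 7], np.tile([50.0, 50.0], (3, 1)), 2.0)
        out = extract_trace(tr, constant_spot_movie, pad_frames=0)
        assert np.allclose(out.raw_trace, 0.0, atol=1e-9)

    def test_argmax_matches_ground_truth_peak(self):
        cfg = noise_free(SimConfig(image_shape=(96, 96), n_puncta=1, seed=23))
        markers = [MarkerSpec("g", 0.0, 10.0), MarkerSpec("r", 0.0, 10.0)]
        movie, gt = simulate_maturation_movie(cfg, markers)
        tr = extract_trace(track_puncta(movie)[0], movie)
        peak_frame = tr.frames[np.argmax(tr.raw_trace[0])]
        true_frame = gt.puncta["peak_time_g"][0] / movie.frame_interval
        assert abs(peak_frame - true_frame) <= 0.5

    def test_uniform_offset_cancelled_by_annulus(self, constant_spot_movie):
        from golgikin.synthetic import MovieStack

        tr0 = track_puncta(constant_spot_movie)[0]
        base = extract_trace(tr0, constant_spot_movie)
        shifted = MovieStack(
            constant_spot_movie.data + 57.0,
            constant_spot_movie.frame_interval,
            list(constant_spot_movie.channel_names),
        )
        out = extract_trace(tr0, shifted)
        assert np.allclose(out.raw_trace, base.raw_trace, atol=1e-6)

    def test_border_disk_trimmed_with_warning(self, constant_spot_movie):
        tr = Track(0, [0, 1], np.tile([1.0, 1.0], (2, 1)), 2.0)
        with pytest.warns(UserWarning, match="trimmed"):
            extract_trace(tr, constant_spot_movie, pad_frames=0)


class TestSelection:
    def test_counts_constructed_truncations(self):
        tracks = []
        for i in range(16):
            tracks.append(_pulse_track(track_id=i))
        for i in range(16, 20):
            tracks.append(_pulse_track(track_id=i, first=0))  # truncated at t=0
        kept = select_analyzable_tracks(tracks, n_frames=61)
        assert len(kept) == 16
        assert all(t.complete for t in kept)

    def test_short_track_excluded(self):
        tr = _pulse_track(first=29, last=32)
        assert select_analyzable_tracks([tr], 61) == []

    def test_full_pulse_included(self):
        tr = _pulse_track()
        assert select_analyzable_tracks([tr], 61) == [tr]

    def test_requires_traces(self):
        tr = Track(0, [1, 2, 3], np.zeros((3, 2)), 2.0)
        with pytest.raises(InvalidParameterError):
            select_analyzable_tracks([tr], 61)


class TestNormalize:
    def test_known_values(self):
        nt = normalize_trace([0, 2, 4], [[2.0, 4.0, 6.0]])
        assert np.allclose(nt.values, [[0.0, 0.5, 1.0]])

    def test_idempotent(self):
        nt = normalize_trace([0, 2, 4], [[0.0, 0.5, 1.0]])
        assert np.allclose(nt.values, [[0.0, 0.5, 1.0]])

    @given(
        arrays(float, (2, 12), elements=st.floats(0, 1e4, width=32)).filter(
            lambda a: (a.max(axis=1) > a.min(axis=1)).all()
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_always_hold(self, raw):
        nt = normalize_trace(np.arange(12) * 2.0, raw)
        assert np.allclose(nt.values.min(axis=1), 0.0)
        assert np.allclose(nt.values.max(axis=1), 1.0)

    def test_flat_channel_raises(self):
        with pytest.raises(DegenerateTraceError):
            normalize_trace([0, 2], [[1.0, 1.0]])


class TestPeakTiming:
    def test_noiseless_gaussian_peak_at_60(self):
        t = np.arange(0, 121, 2.0)
        v = np.exp(-((t - 60.0) ** 2) / (2 * 100.0))
        nt = NormalizedTrace(t, v[None, :])
        assert peak_time(nt, 0) == 60.0
        assert peak_time(nt, 0, smooth_window=1) == peak_time(nt, 0, smooth_window=3)

    def test_tie_breaks_to_earliest(self):
        t = np.arange(0, 62, 2.0)
        v = np.zeros_like(t)
        v[[5, 10]] = 1.0  # equal maxima at t=10 and t=20
        nt = NormalizedTrace(t, v[None, :])
        assert peak_time(nt, 0, smooth_window=1) == 10.0

    def test_even_smooth_window_rejected(self):
        nt = NormalizedTrace(np.arange(4.0), np.ones((1, 4)))
        with pytest.raises(InvalidParameterError):
            peak_time(nt, 0, smooth_window=2)

    def test_identical_channels_give_zero_offset(self):
        tr = _pulse_track(offset_s=0.0)
        nt = normalize_trace(tr.times, tr.raw_trace, tr.channel_names)
        assert peak_to_peak(nt, "green", "red") == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((2, 20)) + 1e-3
        nt = normalize_trace(np.arange(20) * 2.0, vals)
        assert peak_to_peak(nt, 0, 1) == -peak_to_peak(nt, 1, 0)

    def test_designed_offset_recovered_noiselessly(self):
        tr = _pulse_track(offset_s=10.0)
        res = summarize_peak_to_peak([tr], "green", "red")
        assert res.median == 10.0
        assert res.n == 1


class TestAverageTraces:
    def test_identical_tracks_zero_ci_width(self):
        tracks = [_pulse_track(track_id=i) for i in range(5)]
        avg = average_traces(tracks, reference_channel=0)
        mid = np.abs(avg.times).argmin()
        assert avg.times[mid] == 0.0
        assert np.allclose(avg.ci_high - avg.ci_low, 0.0, atol=1e-9)

    def test_reference_channel_peaks_at_zero(self):
        tracks = [_pulse_track(track_id=i, peak_frame=25 + i) for i in range(4)]
        avg = average_traces(tracks, reference_channel=0)
        assert avg.times[np.argmax(avg.mean[0])] == 0.0
        assert np.all(avg.ci_low <= avg.mean + 1e-12)
        assert np.all(avg.mean <= avg.ci_high + 1e-12)

    def test_zero_offset_channels_peak_together(self):
        tracks = [_pulse_track(track_id=i, peak_frame=22 + 2 * i) for i in range(10)]
        avg = average_traces(tracks, reference_channel=0)
        assert avg.times[np.argmax(avg.mean[1])] == 0.0

    def test_insufficient_tracks(self):
        with pytest.raises(InsufficientDataError):
            average_traces([_pulse_track()], 0)


class TestMarkerOrder:
    def _res(self, ref, name, median):
        return PeakToPeakResult(
            per_track=pd.DataFrame({"track_id": [0], "dt_s": [median]}),
            n=1,
            median=median,
            ch_first=ref,
            ch_second=name,
        )

    def test_designed_order_with_coincident_pair(self):
        results = [
            self._res("Mnn9", "Mnn9", 0.0),
            self._res("Mnn9", "Erd1", 0.4),
            self._res("Mnn9", "COPI", 6.2),
            self._res("Mnn9", "Vps74", 12.4),
            self._res("Mnn9", "Sec7", 19.6),
        ]
        assert marker_order(results, 2.0) == [["Mnn9", "Erd1"], ["COPI"], ["Vps74"], ["Sec7"]]

    def test_singleton(self):
        assert marker_order([self._res("Mnn9", "Erd1", 1.0)], 2.0) == [["Erd1"]]

    def test_permutation_invariance(self):
        results = [
            self._res("Mnn9", "Sec7", 19.6),
            self._res("Mnn9", "COPI", 6.2),
            self._res("Mnn9", "Erd1", 0.4),
        ]
        assert marker_order(results, 2.0) == marker_order(results[::-1], 2.0)

    def test_inconsistent_reference_rejected(self):
        with pytest.raises(InvalidParameterError):
            marker_order([self._res("Mnn9", "a", 0.0), self._res("Sec7", "b", 1.0)], 2.0)


def test_end_to_end_offset_recovery_small():
    """Full pipeline on a small default-noise movie recovers a +8 s offset."""
    cfg = SimConfig(image_shape=(128, 128), n_puncta=8, seed=31)
    markers = [MarkerSpec("g", 0.0, 10.0), MarkerSpec("r", 8.0, 10.0)]
    movie, _ = simulate_maturation_movie(cfg, markers)
    report = analyze_movie(movie, reference_channel="g")
    res = report.pairwise["r"]
    assert res.n >= 4
    assert abs(res.median - 8.0) <= 2.0
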