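"""Single-compartment maturation kinetics from two-channel time-lapse movies.

The chain is: detect puncta per frame on the channel-sum image, link them
into tracks by greedy nearest-neighbor association, integrate a small disk
around each track position to get per-channel raw traces (with local annulus
background subtraction), keep only compartments whose full lifetime is
captured, min-max normalize each channel to [0, 1], and estimate the signed
peak-to-peak time between channel pairs as the difference of smoothed-argmax
peak times. Peak-aligned averaged traces with per-timepoint t-distribution
95% CIs summarize the pulse shape, and pairwise medians against a common
reference marker yield the temporal ordering of markers on a maturing
compartment.

Sign convention (stated in every output header): Δt > 0 means the
second-listed channel peaks *later* than the first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateImageError,
    DegenerateTraceError,
    InsufficientDataError,
    InvalidParameterError,
)
from .segmentation import SegmentationParams, otsu_threshold, segment_puncta
from .synthetic import MovieStack

__all__ = [
    "Track",
    "NormalizedTrace",
    "PeakToPeakResult",
    "AveragedTrace",
    "track_puncta",
    "extract_trace",
    "select_analyzable_tracks",
    "normalize_trace",
    "normalize_track",
    "peak_time",
    "peak_to_peak",
    "summarize_peak_to_peak",
    "average_traces",
    "marker_order",
]


@dataclass
class Track:
    """One Golgi compartment followed across frames.

    ``frames`` are strictly increasing frame indices; ``positions`` the
    per-frame (row, col) centroids; ``raw_trace`` (channels x frames) is
    filled by :func:`extract_trace`. ``complete`` is set by
    :func:`select_analyzable_tracks` when the whole lifetime lies inside the
    movie.
    """

    track_id: int
    frames: list[int]
    positions: np.ndarray
    frame_interval: float
    channel_names: list[str] = field(default_factory=list)
    raw_trace: np.ndarray | None = None
    complete: bool = False
    detected_span: tuple[int, int] | None = None  # first/last *detected* frame

    @property
    def det_first(self) -> int:
        return self.detected_span[0] if self.detected_span else self.frames[0]

    @property
    def det_last(self) -> int:
        return self.detected_span[1] if self.detected_span else self.frames[-1]

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.frames, dtype=float) * self.frame_interval

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class NormalizedTrace:
    """Per-channel min-max normalized intensity trace; each channel spans [0, 1]."""

    times: np.ndarray
    values: np.ndarray  # (channels, timepoints)
    channel_names: list[str] = field(default_factory=list)

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise InvalidParameterError(
                    f"unknown channel {channel!r}; have {self.channel_names}"
                ) from None
        return int(channel)


@dataclass
class PeakToPeakResult:
    """Signed peak-to-peak offsets for one channel pair over many tracks.

    Δt = peak_time(second) - peak_time(first): positive when the second
    channel peaks later.
    """

    per_track: pd.DataFrame  # track_id, dt_s
    n: int
    median: float
    ch_first: str
    ch_second: str

    @property
    def distribution(self) -> np.ndarray:
        return self.per_track["dt_s"].to_numpy()


@dataclass
class AveragedTrace:
    """Peak-aligned mean trace with per-timepoint 95% CI.

    ``times`` are seconds relative to the reference-channel peak (t = 0 at
    the peak); arrays are (channels, timepoints); ``n_per_timepoint`` counts
    the tracks contributing at each grid point.
    """

    times: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_tracks: int
    n_per_timepoint: np.ndarray
    channel_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def _detect_centroids(
    img: np.ndarray, params: SegmentationParams, noise_floor_k: float = 5.0
) -> np.ndarray:
    """Per-frame spot detection with a noise-floor guard.

    Otsu assumes a bimodal histogram; on frames where no compartment is
    active it splits the noise into hundreds of spurious blobs. A detection
    frame is accepted only when the Otsu threshold stands above the frame's
    noise floor — median + ``noise_floor_k`` robust spreads (1.4826 x MAD).
    The robust floor is insensitive to the spots themselves (they occupy few
    pixels), while a threshold below it can only be splitting noise.
    """
    try:
        med = float(np.median(img))
        mad = float(np.median(np.abs(img - med)))
        if otsu_threshold(img, params.n_bins) < med + noise_floor_k * 1.4826 * mad:
            return np.empty((0, 2))
        return np.array([o.centroid for o in segment_puncta(img, params)]).reshape(-1, 2)
    except DegenerateImageError:
        return np.empty((0, 2))


def track_puncta(
    movie: MovieStack,
    params: SegmentationParams | None = None,
    max_displacement: float = 3.0,
    max_gap: int = 1,
) -> list[Track]:
    """Detect and link puncta across frames by greedy nearest-neighbor matching.

    Detection runs per frame on the channel-sum image (a compartment is
    visible whenever any of its markers is on). Candidate links between open
    track heads and new detections are accepted closest-pair-first and
    rejected beyond ``max_displacement`` px; a track missing detections for
    more than ``max_gap`` consecutive frames is closed, with its position held
    during the gap. The movie should be preprocessed frame by frame first.
    """
    params = params or SegmentationParams()
    open_tracks: list[dict] = []
    closed: list[dict] = []
    next_id = 0
    for t in range(movie.n_frames):
        dets = _detect_centroids(movie.data[t].sum(axis=0), params)
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        if open_tracks and len(dets):
            heads = np.array([tr["positions"][-1] for tr in open_tracks])
            dist = np.linalg.norm(heads[:, None, :] - dets[None, :, :], axis=2)
            order = np.argsort(dist, axis=None)
            for flat in order:
                i, j = np.unravel_index(flat, dist.shape)
                if dist[i, j] > max_displacement:
                    break
                if i in matched_tracks or j in matched_dets:
                    continue
                matched_tracks.add(int(i))
                matched_dets.add(int(j))
                open_tracks[i]["frames"].append(t)
                open_tracks[i]["positions"].append(dets[j])
                open_tracks[i]["gap"] = 0
        still_open = []
        for i, tr in enumerate(open_tracks):
            if i in matched_tracks:
                still_open.append(tr)
                continue
            tr["gap"] += 1
            if tr["gap"] > max_gap:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        for j in range(len(dets)):
            if j not in matched_dets:
                open_tracks.append(
                    {"id": next_id, "frames": [t], "positions": [dets[j]], "gap": 0}
                )
                next_id += 1
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: (tr["frames"][0], tr["id"]))
    return [
        Track(
            track_id=i,
            frames=tr["frames"],
            positions=np.array(tr["positions"]).reshape(-1, 2),
            frame_interval=movie.frame_interval,
            channel_names=list(movie.channel_names),
        )
        for i, tr in enumerate(closed)
    ]


def _disk_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = yy**2 + xx**2 <= radius**2
    return np.stack([yy[keep], xx[keep]], axis=1)


def _annulus_offsets(r_in: int, r_out: int) -> np.ndarray:
    yy, xx = np.mgrid[-r_out : r_out + 1, -r_out : r_out + 1]
    d2 = yy**2 + xx**2
    keep = (d2 > r_in**2) & (d2 <= r_out**2)
    return np.stack([yy[keep], xx[keep]], axis=1)


def extract_trace(track: Track, movie: MovieStack, radius: int = 3, pad_frames: int = 8) -> Track:
    """Measure per-channel intensity traces along a track.

    For every frame between the track's first and last detection (positions
    linearly interpolated across gaps), the intensity in a disk of ``radius``
    px about the position is integrated, and the local background — the
    median in an annulus radius+2..radius+4 — times the disk area is
    subtracted, clipped at zero. The measurement window is extended by
    ``pad_frames`` beyond the detected lifetime on each side (position held,
    clipped to the movie), so the trace samples its baseline rather than
    stopping at the detection limit. Returns a new Track with contiguous
    frames, ``raw_trace`` filled and ``detected_span`` preserved; disks
    partially outside the image are trimmed with a warning.
    """
    if radius < 1:
        raise InvalidParameterError(f"radius must be >= 1, got {radius}")
    if pad_frames < 0:
        raise InvalidParameterError(f"pad_frames must be >= 0, got {pad_frames}")
    d0, d1 = track.frames[0], track.frames[-1]
    f0 = max(0, d0 - pad_frames)
    f1 = min(movie.n_frames - 1, d1 + pad_frames)
    full = np.arange(f0, f1 + 1)
    rows = np.interp(full, track.frames, track.positions[:, 0])
    cols = np.interp(full, track.frames, track.positions[:, 1])
    disk = _disk_offsets(radius)
    annulus = _annulus_offsets(radius + 2, radius + 4)
    ny, nx = movie.data.shape[2:]
    trace = np.zeros((movie.n_channels, full.size))
    trimmed = False
    for k, (f, r, c) in enumerate(zip(full, rows, cols)):
        ri, ci = int(round(r)), int(round(c))
        dpix = disk + [ri, ci]
        apix = annulus + [ri, ci]
        dkeep = (dpix[:, 0] >= 0) & (dpix[:, 0] < ny) & (dpix[:, 1] >= 0) & (dpix[:, 1] < nx)
        akeep = (apix[:, 0] >= 0) & (apix[:, 0] < ny) & (apix[:, 1] >= 0) & (apix[:, 1] < nx)
        if not dkeep.all():
            trimmed = True
        dpix, apix = dpix[dkeep], apix[akeep]
        for ch in range(movie.n_channels):
            frame = movie.data[f, ch]
            disk_sum = frame[dpix[:, 0], dpix[:, 1]].sum()
            local_bg = np.median(frame[apix[:, 0], apix[:, 1]]) if len(apix) else 0.0
            trace[ch, k] = max(disk_sum - local_bg * len(dpix), 0.0)
    if trimmed:
        warnings.warn(f"track {track.track_id}: measurement disk trimmed at image border")
    return Track(
        track_id=track.track_id,
        frames=list(full),
        positions=np.stack([rows, cols], axis=1),
        frame_interval=movie.frame_interval,
        channel_names=list(track.channel_names) or list(movie.channel_names),
        raw_trace=trace,
        detected_span=(d0, d1),
    )


def select_analyzable_tracks(
    tracks: list[Track], n_frames: int, min_length: int = 5
) -> list[Track]:
    """Keep compartments whose full lifetime was captured in the movie.

    A track is analyzable when it is not truncated at either movie end
    (first detection after frame 0, last before the final frame), spans at
    least ``min_length`` frames, and its traces both rise and fall (first and
    last values below 50% of the maximum). For two-channel movies the
    rise-and-fall test applies to each channel; with more channels it applies
    to the channel-sum trace — the compartment's combined lifetime — since
    with several staggered markers the earliest one is necessarily already
    bright when the compartment first becomes detectable. Tracks must carry
    traces (:func:`extract_trace` first).
    """
    selected = []
    for tr in tracks:
        if tr.raw_trace is None:
            raise InvalidParameterError("tracks must have raw_trace set (run extract_trace)")
        if tr.det_first <= 0 or tr.det_last >= n_frames - 1:
            continue
        if tr.det_last - tr.det_first + 1 < min_length:
            continue
        if tr.raw_trace.shape[0] <= 2:
            profile = tr.raw_trace
        else:
            profile = tr.raw_trace.sum(axis=0, keepdims=True)
        maxima = profile.max(axis=1)
        if np.any(maxima <= 0) or np.any(tr.raw_trace.max(axis=1) <= 0):
            continue
        if np.any(profile[:, 0] >= 0.5 * maxima) or np.any(profile[:, -1] >= 0.5 * maxima):
            continue
        tr.complete = True
        selected.append(tr)
    return selected


# ---------------------------------------------------------------------------
# traces and peak timing
# ---------------------------------------------------------------------------

def normalize_trace(times: np.ndarray, values: np.ndarray, channel_names=None) -> NormalizedTrace:
    """Min-max normalize each channel independently to [0, 1]."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    flat = np.nonzero((hi - lo).ravel() == 0)[0]
    if flat.size:
        raise DegenerateTraceError(f"flat channel(s) {flat.tolist()} cannot be normalized")
    return NormalizedTrace(
        times=np.asarray(times, dtype=float),
        values=(values - lo) / (hi - lo),
        channel_names=list(channel_names or []),
    )


def normalize_track(track: Track) -> NormalizedTrace:
    """Normalized trace of one measured track."""
    if track.raw_trace is None:
        raise InvalidParameterError("track has no raw_trace; run extract_trace first")
    return normalize_trace(track.times, track.raw_trace, track.channel_names)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return values
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def peak_time(
    trace: NormalizedTrace,
    channel: int | str,
    smooth_window: int = 3,
    refine: bool = False,
) -> float:
    """Time of a channel's intensity maximum after moving-average smoothing.

    ``smooth_window`` must be odd (1 disables smoothing); ties go to the
    earliest frame. With ``refine=True`` the peak is interpolated to sub-frame
    precision by a quadratic fit through the argmax and its neighbors.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise InvalidParameterError(f"smooth_window must be odd and >= 1, got {smooth_window}")
    ch = trace.channel_index(channel)
    smoothed = _smooth(trace.values[ch], smooth_window)
    idx = int(np.argmax(smoothed))  # argmax takes the earliest of tied maxima
    if refine and 0 < idx < smoothed.size - 1:
        y0, y1, y2 = smoothed[idx - 1 : idx + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            dt = trace.times[1] - trace.times[0] if trace.times.size > 1 else 0.0
            return float(trace.times[idx] + np.clip(shift, -0.5, 0.5) * dt)
    return float(trace.times[idx])


def peak_to_peak(
    trace: NormalizedTrace,
    ch_first: int | str,
    ch_second: int | str,
    smooth_window: int = 3,
) -> float:
    """Signed peak-to-peak time: peak(second) - peak(first), seconds."""
    return peak_time(trace, ch_second, smooth_window) - peak_time(trace, ch_first, smooth_window)


def summarize_peak_to_peak(
    tracks: list[Track],
    ch_first: int | str = 0,
    ch_second: int | str = 1,
    smooth_window: int = 3,
) -> PeakToPeakResult:
    """Per-track peak-to-peak offsets for one channel pair, with the median."""
    rows = []
    names = ("", "")
    for tr in tracks:
        try:
            nt = normalize_track(tr)
        except DegenerateTraceError:
            warnings.warn(f"track {tr.track_id}: flat channel, skipped")
            continue
        names = (
            nt.channel_names[nt.channel_index(ch_first)] if nt.channel_names else str(ch_first),
            nt.channel_names[nt.channel_index(ch_second)] if nt.channel_names else str(ch_second),
        )
        rows.append({"track_id": tr.track_id, "dt_s": peak_to_peak(nt, ch_first, ch_second, smooth_window)})
    per_track = pd.DataFrame(rows, columns=["track_id", "dt_s"])
    if per_track.empty:
        warnings.warn("no analyzable tracks; empty peak-to-peak result")
        return PeakToPeakResult(per_track, 0, float("nan"), names[0], names[1])
    return PeakToPeakResult(
        per_track=per_track,
        n=len(per_track),
        median=float(per_track["dt_s"].median()),
        ch_first=names[0],
        ch_second=names[1],
    )


def average_traces(
    tracks: list[Track],
    reference_channel: int | str = 0,
    smooth_window: int = 3,
    level: float = 0.95,
) -> AveragedTrace:
    """Peak-aligned averaged normalized traces with per-timepoint 95% CI.

    Each track's normalized trace is shifted so its reference-channel peak
    sits at t = 0, interpolated onto a common grid at the frame interval, and
    averaged per timepoint per channel; the CI is two-sided from the
    t-distribution over the tracks contributing at that timepoint. Timepoints
    with fewer than 2 contributing tracks are dropped.
    """
    if len(tracks) < 2:
        raise InsufficientDataError("averaging needs at least 2 tracks")
    dt = tracks[0].frame_interval
    shifted: list[NormalizedTrace] = []
    for tr in tracks:
        nt = normalize_track(tr)
        ref_peak = peak_time(nt, reference_channel, smooth_window)
        shifted.append(NormalizedTrace(nt.times - ref_peak, nt.values, nt.channel_names))
    tmin = min(s.times[0] for s in shifted)
    tmax = max(s.times[-1] for s in shifted)
    grid = dt * np.arange(round(tmin / dt), round(tmax / dt) + 1)
    n_ch = shifted[0].values.shape[0]
    stack = np.full((len(shifted), n_ch, grid.size), np.nan)
    for i, s in enumerate(shifted):
        inside = (grid >= s.times[0] - 1e-9) & (grid <= s.times[-1] + 1e-9)
        for ch in range(n_ch):
            stack[i, ch, inside] = np.interp(grid[inside], s.times, s.values[ch])
    counts = np.sum(~np.isnan(stack[:, 0, :]), axis=0)
    keep = counts >= 2
    grid, stack, counts = grid[keep], stack[:, :, keep], counts[keep]
    mean = np.nanmean(stack, axis=0)
    sd = np.nanstd(stack, axis=0, ddof=1)
    tq = stats.t.ppf(0.5 + level / 2.0, np.maximum(counts - 1, 1))
    half = tq * sd / np.sqrt(counts)
    return AveragedTrace(
        times=grid,
        mean=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        n_tracks=len(tracks),
        n_per_timepoint=counts,
        channel_names=list(shifted[0].channel_names),
    )


def marker_order(
    results: list[PeakToPeakResult], frame_interval: float
) -> list[list[str]]:
    """Temporal ordering of markers from pairwise offsets to a common reference.

    All results must share the same first (reference) channel. Markers are
    sorted by their median Δt to the reference, ascending; markers whose
    medians lie within one frame interval of a group's first member are
    reported together as coincident. Returns a list of coincident groups in
    temporal order.
    """
    if not results:
        return []
    refs = {r.ch_first for r in results}
    if len(refs) != 1:
        raise InvalidParameterError(f"results mix reference markers: {sorted(refs)}")
    entries = sorted(
        ((r.median, r.ch_second) for r in results), key=lambda e: (e[0], e[1])
    )
    groups: list[list[str]] = []
    group_start = None
    for med, name in entries:
        if group_start is not None and med - group_start <= frame_interval:
            groups[-1].append(name)
        else:
            groups.append([name])
            group_start = med
    return groups
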