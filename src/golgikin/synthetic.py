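"""Synthetic two-channel microscopy data with known ground truth.

This module generates the three kinds of images the analysis pipeline consumes,
with the statistical structure of spinning-disk yeast Golgi data:

* **Maturation movies** — fixed-interval time-lapse stacks in which each Golgi
  punctum carries one temporal intensity pulse per marker channel, the pulses
  staggered by designed offsets (early markers peak before late ones on a
  maturing compartment).
* **Colocalization snapshots** — single-frame two-channel fields of
  diffraction-limited puncta that are either coincident between the channels or
  present in only one.
* **Whole-cell images** — disk-shaped cells with an interior vacuole disk, the
  cell's total fluorescence partitioned between vacuole and cytoplasm by a
  designed fraction, with aligned label masks.

Every generator returns a :class:`GroundTruth` recording true positions, true
per-marker peak times, true coincidence labels, true vacuolar fractions and the
coordinates of injected hot pixels, so downstream estimates can be scored
exactly.

Image formation model: a flat background plus 2-D Gaussian spots (isotropic
PSF approximation, spot *peak* pixel value = marker pulse value), multiplied by
a smooth illumination field, then optional Poisson shot noise, additive
Gaussian read noise and salt-type hot pixels. All randomness flows from a
single integer seed through independent child generators, so disabling one
noise source never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidParameterError

__all__ = [
    "MarkerSpec",
    "SimConfig",
    "GroundTruth",
    "MovieStack",
    "marker_pulse",
    "simulate_maturation_movie",
    "simulate_coloc_snapshot",
    "simulate_cell_image",
    "noise_free",
    "GOLGI_MARKER_OFFSETS",
]

#: Designed peak offsets (seconds, relative to the early marker Mnn9) used by
#: the demo and the ordering-recovery experiments: Erd1 arrives with the early
#: marker, COPI, Vps74 and the late marker Sec7 progressively later.
GOLGI_MARKER_OFFSETS = {"Mnn9": 0.0, "Erd1": 0.0, "COPI": 6.0, "Vps74": 12.0, "Sec7": 20.0}


@dataclass(frozen=True)
class MarkerSpec:
    """One fluorescent marker channel of a maturation movie.

    Parameters
    ----------
    name : str
        Marker label, e.g. ``"Mnn9"`` or ``"Erd1"``.
    peak_offset : float
        Seconds between this marker's intensity peak and the reference
        marker's peak on the same compartment. The first listed marker with
        offset 0 is the reference.
    pulse_width : float
        Temporal Gaussian sigma of the intensity pulse, seconds.
    amplitude : float
        Peak pixel value (counts) of the spot at pulse maximum.
    """

    name: str
    peak_offset: float
    pulse_width: float = 10.0
    amplitude: float = 600.0

    def __post_init__(self) -> None:
        if self.pulse_width <= 0:
            raise InvalidParameterError(f"pulse_width must be > 0, got {self.pulse_width}")
        if self.amplitude <= 0:
            raise InvalidParameterError(f"amplitude must be > 0, got {self.amplitude}")


@dataclass(frozen=True)
class SimConfig:
    """Scene and acquisition parameters shared by all generators.

    Defaults emulate the acquisition regime of spinning-disk yeast imaging:
    2 s frame interval over 2 min, ~1.5 px PSF sigma, a camera background of
    ~100 counts with shot noise and a few counts of read noise, occasional
    hot pixels, and a smooth multiplicative illumination gradient.
    """

    image_shape: tuple[int, int] = (160, 160)
    n_puncta: int = 10
    frame_interval: float = 2.0  # s
    duration: float = 120.0  # s
    psf_sigma: float = 1.5  # px
    hot_pixel_rate: float = 1e-4  # per pixel per frame
    hot_pixel_value: float = 4000.0  # counts
    illum_amplitude: float = 0.15  # relative
    read_noise_sigma: float = 3.0  # counts
    background_level: float = 100.0  # counts
    shot_noise: bool = True
    seed: int = 0
    min_separation: float = 12.0  # px between punctum centres
    jitter_sigma: float = 0.0  # px per frame of Brownian position jitter

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise InvalidParameterError("duration must be >= frame_interval")
        if self.psf_sigma <= 0:
            raise InvalidParameterError("psf_sigma must be > 0")
        if not (0 <= self.hot_pixel_rate < 0.01):
            raise InvalidParameterError("hot_pixel_rate must lie in [0, 0.01)")

    @property
    def n_frames(self) -> int:
        return math.floor(self.duration / self.frame_interval) + 1

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class MovieStack:
    """A time-ordered multi-channel pixel array with acquisition metadata.

    ``data`` has axes (T, C, Y, X); ``frame_interval`` is in seconds and
    ``channel_names`` maps channel index to marker label.
    """

    data: np.ndarray
    frame_interval: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InvalidParameterError(
                f"movie data must have axes (T, C, Y, X); got ndim={self.data.ndim}"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise InvalidParameterError("channel_names length must match channel axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise InvalidParameterError(
                    f"unknown channel {channel!r}; have {self.channel_names}"
                ) from None
        if not 0 <= channel < self.n_channels:
            raise InvalidParameterError(f"channel index {channel} out of range")
        return int(channel)


def _empty_df(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


@dataclass
class GroundTruth:
    """The simulator's record of everything the analysis tries to recover.

    ``puncta`` — one row per punctum: id, (row, col) position, birth time, and
    one ``peak_time_<marker>`` column per marker (movies), or a ``channel``
    column (snapshots).
    ``coloc_pairs`` — green id, matching red id (nullable) and designed
    overlap fraction in [0, 1].
    ``cell_records`` — cell id and true vacuolar fraction in [0, 1].
    ``hot_pixels`` — frame, channel, row, col of every injected hot pixel.
    """

    puncta: pd.DataFrame = field(default_factory=lambda: _empty_df(["punctum_id", "row", "col"]))
    coloc_pairs: pd.DataFrame = field(
        default_factory=lambda: _empty_df(["green_id", "red_id", "overlap_fraction"])
    )
    cell_records: pd.DataFrame = field(
        default_factory=lambda: _empty_df(["cell_id", "vacuolar_fraction"])
    )
    hot_pixels: pd.DataFrame = field(
        default_factory=lambda: _empty_df(["frame", "channel", "row", "col"])
    )

    def peak_time(self, punctum_id: int, marker: str) -> float:
        row = self.puncta.loc[self.puncta["punctum_id"] == punctum_id]
        return float(row[f"peak_time_{marker}"].iloc[0])


def marker_pulse(t, peak_time: float, width: float, amplitude: float):
    """Gaussian temporal intensity pulse of one marker on one compartment.

    Returns ``amplitude * exp(-(t - peak_time)^2 / (2 width^2))`` — a strictly
    positive, symmetric pulse with its unique maximum at ``peak_time``.
    ``t`` may be a scalar or array of times in seconds.
    """
    if width <= 0:
        raise InvalidParameterError(f"pulse width must be > 0, got {width}")
    if amplitude <= 0:
        raise InvalidParameterError(f"pulse amplitude must be > 0, got {amplitude}")
    t = np.asarray(t, dtype=float)
    out = amplitude * np.exp(-((t - peak_time) ** 2) / (2.0 * width**2))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# scene construction helpers
# ---------------------------------------------------------------------------

def _place_points(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    min_separation: float,
    margin: float,
) -> np.ndarray:
    """Dart-throwing placement of n points with pairwise min separation."""
    ny, nx = shape
    if ny - 2 * margin <= 0 or nx - 2 * margin <= 0:
        raise ConfigurationError("image too small for the requested margin")
    pts: list[np.ndarray] = []
    max_tries = 5000 * max(n, 1)
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise ConfigurationError(
                f"could not place {n} puncta with min separation {min_separation} px "
                f"in a {ny}x{nx} image"
            )
        cand = np.array(
            [rng.uniform(margin, ny - margin), rng.uniform(margin, nx - margin)]
        )
        if all(np.hypot(*(cand - p)) >= min_separation for p in pts):
            pts.append(cand)
    return np.array(pts).reshape(n, 2)


def _add_spot(frame: np.ndarray, row: float, col: float, sigma: float, peak: float) -> None:
    """Add a 2-D Gaussian spot (peak pixel value = ``peak``) in place."""
    if peak <= 0:
        return
    ny, nx = frame.shape
    half = int(math.ceil(4 * sigma)) + 1
    r0, r1 = max(0, int(row) - half), min(ny, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(nx, int(col) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    frame[r0:r1, c0:c1] += peak * np.exp(
        -((yy - row) ** 2 + (xx - col) ** 2) / (2.0 * sigma**2)
    )


def _illumination_field(
    rng: np.random.Generator, shape: tuple[int, int], amplitude: float
) -> np.ndarray:
    """Smooth multiplicative field: 1 + amplitude * (plane + wide Gaussian bump).

    Spatial scale is at least a quarter of the image width, so a large-sigma
    background subtraction removes it. Mean is ~1; the field consumes the same
    rng draws whether or not amplitude is zero, keeping other draws aligned.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    gy, gx = rng.uniform(-1.0, 1.0, size=2)
    plane = gy * (yy / ny - 0.5) + gx * (xx / nx - 0.5)
    cy, cx = rng.uniform(0.25, 0.75, size=2)
    scale = rng.uniform(0.25, 0.5) * max(ny, nx)
    bump = np.exp(-(((yy - cy * ny) ** 2 + (xx - cx * nx) ** 2)) / (2.0 * scale**2))
    f = plane + bump
    f -= f.mean()
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    return 1.0 + amplitude * f


def _apply_noise(
    scene: np.ndarray,
    config: SimConfig,
    noise_rng: np.random.Generator,
    hot_rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson + read noise + hot pixels for one frame; returns (frame, hot coords)."""
    if config.shot_noise:
        frame = noise_rng.poisson(np.clip(scene, 0, None)).astype(float)
    else:
        frame = scene.copy()
    if config.read_noise_sigma > 0:
        frame += noise_rng.normal(0.0, config.read_noise_sigma, size=frame.shape)
    if config.hot_pixel_rate > 0:
        mask = hot_rng.random(frame.shape) < config.hot_pixel_rate
        frame[mask] = config.hot_pixel_value
        hot = np.argwhere(mask)
    else:
        hot = np.empty((0, 2), dtype=int)
    return np.clip(frame, 0, None), hot


def _spawn_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Independent child generators for geometry, pixel noise and hot pixels.

    Separate streams mean that turning one noise source off leaves the other
    draws — and hence the rest of the image — bit-identical.
    """
    base = np.random.default_rng(seed)
    scene_rng, noise_rng, hot_rng = base.spawn(3)
    return scene_rng, noise_rng, hot_rng


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_maturation_movie(
    config: SimConfig, markers: list[MarkerSpec]
) -> tuple[MovieStack, GroundTruth]:
    """Simulate a two-or-more-channel maturation movie with known kinetics.

    Each punctum sits at a fixed position (plus optional Brownian jitter) and
    carries one temporal Gaussian pulse per marker, the pulses offset by each
    marker's ``peak_offset`` from a per-punctum reference peak time. Reference
    peak times are drawn uniformly within the window that keeps every
    marker's full pulse (peak ± 2·width) inside the movie.

    Returns the movie (axes T, C, Y, X; one channel per marker, in input
    order) and a :class:`GroundTruth` with positions and true peak times.
    """
    if config.n_puncta < 1:
        raise ConfigurationError("need at least one punctum")
    if len(markers) < 2:
        raise ConfigurationError("need at least two markers")
    if not any(m.peak_offset == 0 for m in markers):
        raise ConfigurationError("at least one marker must have peak_offset 0 (the reference)")

    lo = max(2 * m.pulse_width - m.peak_offset for m in markers)
    hi = min(config.duration - m.peak_offset - 2 * m.pulse_width for m in markers)
    if lo > hi:
        worst = max(markers, key=lambda m: m.peak_offset + 4 * m.pulse_width)
        raise ConfigurationError(
            f"marker {worst.name!r}: pulse (offset {worst.peak_offset} s, width "
            f"{worst.pulse_width} s) cannot fit inside a {config.duration} s movie"
        )

    scene_rng, noise_rng, hot_rng = _spawn_streams(config.seed)
    margin = max(8.0, 4 * config.psf_sigma + 2)
    positions = _place_points(
        scene_rng, config.image_shape, config.n_puncta, config.min_separation, margin
    )
    ref_peaks = scene_rng.uniform(lo, hi, size=config.n_puncta)
    illum = _illumination_field(scene_rng, config.image_shape, config.illum_amplitude)

    n_frames = config.n_frames
    # Per-frame positions: static unless Brownian jitter is enabled.
    if config.jitter_sigma > 0:
        steps = scene_rng.normal(0.0, config.jitter_sigma, size=(n_frames - 1, config.n_puncta, 2))
        traj = np.concatenate([positions[None], positions[None] + np.cumsum(steps, axis=0)])
    else:
        traj = np.broadcast_to(positions, (n_frames, config.n_puncta, 2))

    data = np.empty((n_frames, len(markers), *config.image_shape))
    hot_records: list[tuple[int, int, int, int]] = []
    for t_idx, t in enumerate(config.frame_times):
        for c, m in enumerate(markers):
            scene = np.full(config.image_shape, float(config.background_level))
            for p in range(config.n_puncta):
                peak = marker_pulse(t, ref_peaks[p] + m.peak_offset, m.pulse_width, m.amplitude)
                _add_spot(scene, traj[t_idx, p, 0], traj[t_idx, p, 1], config.psf_sigma, peak)
            scene *= illum
            frame, hot = _apply_noise(scene, config, noise_rng, hot_rng)
            data[t_idx, c] = frame
            hot_records.extend((t_idx, c, r, cc) for r, cc in hot)

    puncta = pd.DataFrame(
        {
            "punctum_id": np.arange(config.n_puncta),
            "row": positions[:, 0],
            "col": positions[:, 1],
            "birth_time": [
                min(rp + m.peak_offset - 2 * m.pulse_width for m in markers) for rp in ref_peaks
            ],
        }
    )
    for m in markers:
        puncta[f"peak_time_{m.name}"] = ref_peaks + m.peak_offset

    gt = GroundTruth(
        puncta=puncta,
        hot_pixels=pd.DataFrame(hot_records, columns=["frame", "channel", "row", "col"]),
    )
    movie = MovieStack(data, config.frame_interval, [m.name for m in markers])
    return movie, gt


def simulate_coloc_snapshot(
    config: SimConfig,
    n_coincident: int,
    n_green_only: int,
    n_red_only: int,
    amplitude: float = 600.0,
    jitter: float = 0.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate a single-frame two-channel colocalization field.

    ``n_coincident`` puncta appear at the same position in both channels
    (optionally displaced by ``jitter`` px in the red channel); the rest are
    present in only one channel. Returns a (2, Y, X) image — channel 0 green,
    channel 1 red — and a ground truth whose ``coloc_pairs`` table labels each
    green punctum with designed overlap fraction 1 (coincident) or 0.
    """
    total = n_coincident + n_green_only + n_red_only
    if total < 1:
        raise ConfigurationError("need at least one punctum")
    for name, v in [("n_coincident", n_coincident), ("n_green_only", n_green_only), ("n_red_only", n_red_only)]:
        if v < 0:
            raise ConfigurationError(f"{name} must be >= 0")

    scene_rng, noise_rng, hot_rng = _spawn_streams(config.seed)
    margin = max(8.0, 4 * config.psf_sigma + 2)
    sites = _place_points(scene_rng, config.image_shape, total, config.min_separation, margin)
    illum = _illumination_field(scene_rng, config.image_shape, config.illum_amplitude)

    rows: list[dict] = []
    pairs: list[dict] = []
    green_scene = np.full(config.image_shape, float(config.background_level))
    red_scene = np.full(config.image_shape, float(config.background_level))
    pid = 0
    for i in range(n_coincident):
        r, c = sites[i]
        if jitter > 0:
            dr, dc = scene_rng.normal(0.0, jitter, size=2)
        else:
            dr = dc = 0.0
        _add_spot(green_scene, r, c, config.psf_sigma, amplitude)
        _add_spot(red_scene, r + dr, c + dc, config.psf_sigma, amplitude)
        rows.append({"punctum_id": pid, "channel": "green", "row": r, "col": c})
        rows.append({"punctum_id": pid + 1, "channel": "red", "row": r + dr, "col": c + dc})
        pairs.append({"green_id": pid, "red_id": pid + 1, "overlap_fraction": 1.0})
        pid += 2
    for i in range(n_coincident, n_coincident + n_green_only):
        r, c = sites[i]
        _add_spot(green_scene, r, c, config.psf_sigma, amplitude)
        rows.append({"punctum_id": pid, "channel": "green", "row": r, "col": c})
        pairs.append({"green_id": pid, "red_id": None, "overlap_fraction": 0.0})
        pid += 1
    for i in range(n_coincident + n_green_only, total):
        r, c = sites[i]
        _add_spot(red_scene, r, c, config.psf_sigma, amplitude)
        rows.append({"punctum_id": pid, "channel": "red", "row": r, "col": c})
        pid += 1

    image = np.empty((2, *config.image_shape))
    hot_records: list[tuple[int, int, int, int]] = []
    for ch, scene in enumerate((green_scene, red_scene)):
        frame, hot = _apply_noise(scene * illum, config, noise_rng, hot_rng)
        image[ch] = frame
        hot_records.extend((0, ch, r, c) for r, c in hot)

    gt = GroundTruth(
        puncta=pd.DataFrame(rows),
        coloc_pairs=pd.DataFrame(pairs, columns=["green_id", "red_id", "overlap_fraction"]),
        hot_pixels=pd.DataFrame(hot_records, columns=["frame", "channel", "row", "col"]),
    )
    return image, gt


def simulate_cell_image(
    config: SimConfig,
    n_cells: int,
    vacuolar_fraction,
    cell_radius: float = 18.0,
    vacuole_radius_fraction: float = 0.45,
    total_flux: float = 2e5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Simulate a field of disk cells with interior vacuole disks.

    Each cell's total fluorescence ``total_flux`` is partitioned so that the
    vacuole disk holds ``vacuolar_fraction`` of it (uniform per-pixel density
    inside each compartment) before background, illumination and noise.
    ``vacuolar_fraction`` may be a scalar or a length-``n_cells`` sequence.

    Returns (image, cell label mask, vacuole label mask, ground truth); masks
    use 0 for background and the 1-based cell id elsewhere.
    """
    if n_cells < 1:
        raise ConfigurationError("need at least one cell")
    fractions = np.broadcast_to(np.asarray(vacuolar_fraction, dtype=float), (n_cells,)).copy()
    if np.any((fractions < 0) | (fractions > 1)):
        raise ConfigurationError("vacuolar_fraction must lie in [0, 1]")
    vac_radius = vacuole_radius_fraction * cell_radius
    if vac_radius >= cell_radius:
        raise ConfigurationError(
            f"vacuole (radius {vac_radius:.1f} px) does not fit inside the cell "
            f"(radius {cell_radius:.1f} px)"
        )

    scene_rng, noise_rng, hot_rng = _spawn_streams(config.seed)
    margin = cell_radius + 2
    centers = _place_points(
        scene_rng, config.image_shape, n_cells, 2 * cell_radius + 4, margin
    )
    illum = _illumination_field(scene_rng, config.image_shape, config.illum_amplitude)

    ny, nx = config.image_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    scene = np.full(config.image_shape, float(config.background_level))
    cell_mask = np.zeros(config.image_shape, dtype=np.int32)
    vac_mask = np.zeros(config.image_shape, dtype=np.int32)
    records = []
    for i, ((r, c), frac) in enumerate(zip(centers, fractions), start=1):
        d2 = (yy - r) ** 2 + (xx - c) ** 2
        in_cell = d2 <= cell_radius**2
        in_vac = d2 <= vac_radius**2
        cell_mask[in_cell] = i
        vac_mask[in_vac] = i
        cyto = in_cell & ~in_vac
        n_vac, n_cyto = int(in_vac.sum()), int(cyto.sum())
        if n_vac:
            scene[in_vac] += frac * total_flux / n_vac
        if n_cyto:
            scene[cyto] += (1.0 - frac) * total_flux / n_cyto
        records.append({"cell_id": i, "vacuolar_fraction": float(frac)})

    image, hot = _apply_noise(scene * illum, config, noise_rng, hot_rng)
    gt = GroundTruth(
        cell_records=pd.DataFrame(records),
        hot_pixels=pd.DataFrame(
            [(0, 0, r, c) for r, c in hot], columns=["frame", "channel", "row", "col"]
        ),
    )
    return image, cell_mask, vac_mask, gt


def noise_free(config: SimConfig) -> SimConfig:
    """A copy of ``config`` with every stochastic corruption disabled."""
    return replace(
        config,
        shot_noise=False,
        read_noise_sigma=0.0,
        hot_pixel_rate=0.0,
        illum_amplitude=0.0,
    )
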