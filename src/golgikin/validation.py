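"""Ground-truth recovery experiments that validate the pipeline end to end.

Each function simulates data under the study conditions the pipeline is
designed for — 2 s frames over 2 min movies, ~250-punctum colocalization
pools, 3 x ~25-cell vacuolar replicates — runs the full analysis, and scores
the result against the simulator's ground truth. The experiments are used by
the test suite and by ``scripts/acceptance.py``; every one is deterministic
given its seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .colocalization import colocalization_profile
from .kinetics import marker_order, normalize_track, peak_time
from .pipeline import analyze_movie
from .preprocess import preprocess_image, remove_hot_pixels
from .segmentation import otsu_threshold
from .synthetic import (
    GOLGI_MARKER_OFFSETS,
    MarkerSpec,
    SimConfig,
    noise_free,
    simulate_cell_image,
    simulate_coloc_snapshot,
    simulate_maturation_movie,
)
from .vacuolar import batch_vacuolar_summary, vacuolar_percentages

__all__ = [
    "brute_force_otsu",
    "zero_offset_experiment",
    "ordering_experiment",
    "otsu_oracle_experiment",
    "coloc_experiment",
    "hot_pixel_experiment",
    "vacuolar_experiment",
    "ci_coverage_experiment",
]

PULSE_WIDTH_S = 10.0  # temporal sigma of the marker pulses, seconds


def _seed_from(seed: int, offset: int) -> int:
    return int((seed * 1000 + offset) % (2**31 - 1))


# ---------------------------------------------------------------------------
# kinetics recovery
# ---------------------------------------------------------------------------

def _movie_config(seed: int, n_puncta: int, shape=(160, 160)) -> SimConfig:
    return SimConfig(image_shape=shape, n_puncta=n_puncta, seed=seed)


def zero_offset_experiment(seed: int, n_puncta: int = 16) -> dict:
    """Two markers peaking simultaneously: the recovered median offset should be ~0.

    Simulates one 2 min movie (2 s frames, default noise) of ``n_puncta``
    compartments carrying a green and a red marker with identical peak times,
    and reports the median peak-to-peak time over the analyzable tracks.
    """
    markers = [MarkerSpec("Erd1", 0.0, PULSE_WIDTH_S), MarkerSpec("Mnn9", 0.0, PULSE_WIDTH_S)]
    movie, _ = simulate_maturation_movie(_movie_config(seed, n_puncta), markers)
    report = analyze_movie(movie, reference_channel="Erd1")
    res = report.pairwise["Mnn9"]
    return {"median_dt_s": res.median, "n_tracks": res.n}


def ordering_experiment(
    seed: int,
    n_replicates: int = 20,
    n_puncta: int = 24,
    offsets: dict[str, float] | None = None,
    tolerance_s: float = 2.0,
) -> dict:
    """Recovery of the designed temporal marker ordering, replicated.

    Scores each replicate as a success when every pairwise median is within
    ``tolerance_s`` of its design and the recovered order is
    (Erd1 with Mnn9) < COPI < Vps74 < Sec7. Each condition is — as in
    two-color live imaging — its own two-channel movie of the reference
    marker plus one other marker, analyzed by the full pipeline; the
    pairwise medians are then combined by
    :func:`golgikin.kinetics.marker_order`.
    """
    offsets = offsets or GOLGI_MARKER_OFFSETS
    ref = next(iter(offsets))
    expected_first = {name for name, off in offsets.items() if off == 0}
    expected_rest = [
        [name] for name, off in sorted(offsets.items(), key=lambda kv: kv[1]) if off > 0
    ]
    successes = 0
    medians: dict[str, list[float]] = {name: [] for name in offsets if name != ref}
    n_tracks = []
    for rep in range(n_replicates):
        results = []
        ok = True
        for j, (name, off) in enumerate(x for x in offsets.items() if x[0] != ref):
            pair = [MarkerSpec(ref, 0.0, PULSE_WIDTH_S), MarkerSpec(name, off, PULSE_WIDTH_S)]
            cfg = _movie_config(_seed_from(seed, 10 * rep + j), n_puncta)
            movie, _ = simulate_maturation_movie(cfg, pair)
            report = analyze_movie(movie, reference_channel=ref)
            res = report.pairwise[name]
            results.append(res)
            medians[name].append(res.median)
            n_tracks.append(res.n)
            if res.n == 0 or abs(res.median - off) > tolerance_s:
                ok = False
            if j == 0:
                results.append(report.pairwise[ref])  # reference vs itself: 0 s
        order = marker_order([r for r in results if r.n > 0], 2.0)
        order_ok = (
            len(order) == 1 + len(expected_rest)
            and set(order[0]) == expected_first
            and order[1:] == expected_rest
        )
        if ok and order_ok:
            successes += 1
    return {
        "n_replicates": n_replicates,
        "successes": successes,
        "median_offsets_s": {k: float(np.median(v)) for k, v in medians.items()},
        "mean_n_tracks": float(np.mean(n_tracks)),
    }


# ---------------------------------------------------------------------------
# Otsu oracle
# ---------------------------------------------------------------------------

def brute_force_otsu(img: np.ndarray) -> float:
    """Exhaustive Otsu: try every unique pixel value as the threshold.

    Independent of the production implementation: classes are formed by
    direct masking and their weights/means computed with plain array
    arithmetic, the between-class variance w0*w1*(mu0-mu1)^2 maximized by
    linear scan with ties going to the lower threshold.
    """
    vals = np.asarray(img, dtype=float).ravel()
    best_var, best_thr = -1.0, None
    for cand in np.unique(vals)[:-1]:
        low = vals[vals <= cand]
        high = vals[vals > cand]
        w0 = low.size / vals.size
        w1 = high.size / vals.size
        var = w0 * w1 * (low.mean() - high.mean()) ** 2
        if var > best_var:
            best_var, best_thr = var, float(cand)
    return best_thr


def otsu_oracle_experiment(seed: int, n_images: int = 50, shape=(32, 32)) -> dict:
    """Production Otsu vs exhaustive search on random 8-bit images."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_images):
        img = rng.integers(0, 256, size=shape)
        if otsu_threshold(img) == brute_force_otsu(img):
            agree += 1
    return {"n_images": n_images, "agreement_rate": agree / n_images}


# ---------------------------------------------------------------------------
# colocalization recovery
# ---------------------------------------------------------------------------

def _snapshot_config(seed: int) -> SimConfig:
    return SimConfig(image_shape=(256, 256), seed=seed)


def _profile_from_snapshots(configs_and_counts, seed: int):
    images = []
    for cfg, (n_co, n_g, n_r) in configs_and_counts:
        image, _ = simulate_coloc_snapshot(cfg, n_co, n_g, n_r)
        images.append(np.stack([preprocess_image(ch) for ch in image]))
    return colocalization_profile(images, seed=_seed_from(seed, 777))


def coloc_experiment(seed: int, n_fields: int = 5) -> dict:
    """Object-based colocalization recovery at the ~250-punctum scale.

    Three designs: (a) ``n_fields`` default-noise fields of 40 coincident +
    10 green-only puncta each — 250 green puncta pooled, designed mean
    overlap 0.8; (b) noise-free fully coincident fields — median must be 1;
    (c) noise-free fully disjoint fields — median must be ~0.
    """
    mixed = _profile_from_snapshots(
        [(_snapshot_config(_seed_from(seed, i)), (40, 10, 0)) for i in range(n_fields)],
        seed,
    )
    coincident = _profile_from_snapshots(
        [(noise_free(_snapshot_config(_seed_from(seed, 100 + i))), (25, 0, 0)) for i in range(2)],
        seed,
    )
    disjoint = _profile_from_snapshots(
        [(noise_free(_snapshot_config(_seed_from(seed, 200 + i))), (0, 25, 25)) for i in range(2)],
        seed,
    )
    return {
        "mixed_mean": mixed.mean,
        "mixed_median": mixed.median,
        "mixed_n": mixed.n_puncta,
        "coincident_median": coincident.median,
        "disjoint_median": disjoint.median,
    }


# ---------------------------------------------------------------------------
# hot-pixel repair
# ---------------------------------------------------------------------------

def hot_pixel_experiment(seed: int, n_fields: int = 5, rate: float = 1e-3) -> dict:
    """Selective median repair scored against the impulse-free reference.

    Sparse noise-free fields (10 puncta per 512x512 frame) are simulated twice
    from the same seed, with and without hot pixels; thanks to independent
    noise streams the two differ only at the injected impulses. Scores the
    fraction of impulses restored to within 1 count of the reference, and
    verifies that the impulse-free image passes through the filter unchanged.
    """
    n_hot = n_repaired = 0
    passthrough = True
    for i in range(n_fields):
        cfg = replace(
            noise_free(SimConfig(image_shape=(512, 512), seed=_seed_from(seed, i))),
            hot_pixel_rate=rate,
        )
        image, gt = simulate_coloc_snapshot(cfg, 5, 3, 2)
        ref_image, _ = simulate_coloc_snapshot(replace(cfg, hot_pixel_rate=0.0), 5, 3, 2)
        for ch in range(2):
            repaired = remove_hot_pixels(image[ch])
            coords = gt.hot_pixels.query("channel == @ch")[["row", "col"]].to_numpy()
            n_hot += len(coords)
            err = np.abs(repaired[coords[:, 0], coords[:, 1]] - ref_image[ch][coords[:, 0], coords[:, 1]])
            n_repaired += int((err <= 1.0).sum())
            if not np.array_equal(remove_hot_pixels(ref_image[ch]), ref_image[ch]):
                passthrough = False
    return {
        "n_hot_pixels": n_hot,
        "repair_rate": n_repaired / n_hot if n_hot else float("nan"),
        "passthrough_unchanged": passthrough,
    }


# ---------------------------------------------------------------------------
# vacuolar recovery
# ---------------------------------------------------------------------------

def vacuolar_experiment(
    seed: int, n_replicates: int = 3, n_cells: int = 25, fraction: float = 0.40
) -> dict:
    """Recovery of a designed vacuolar fraction over replicated cell fields."""
    frames = []
    for rep in range(n_replicates):
        cfg = SimConfig(image_shape=(512, 512), seed=_seed_from(seed, 300 + rep))
        image, cells, vacs, _ = simulate_cell_image(cfg, n_cells, fraction)
        frames.append(vacuolar_percentages(image, cells, vacs, replicate_id=f"rep{rep + 1}"))
    import pandas as pd

    summary = batch_vacuolar_summary(pd.concat(frames, ignore_index=True))
    return {
        "grand_mean_pct": summary.grand_mean,
        "sd_across_replicates_pct": summary.sd_across_replicates,
        "n_cells": summary.n_cells,
        "designed_pct": 100.0 * fraction,
    }


# ---------------------------------------------------------------------------
# averaged-trace CI coverage
# ---------------------------------------------------------------------------

def ci_coverage_experiment(seed: int, n_sims: int = 100, n_puncta: int = 12) -> dict:
    """Does the averaged-trace 95% CI cover the true noiseless pulse?

    For each simulation, a ~10-track zero-offset movie is analyzed and the
    per-timepoint CI of the peak-aligned average is compared with the true
    normalized pulse value at the same absolute times (each track's truth is
    the analytic Gaussian pulse, normalized over that track's observed
    support). Interior timepoints are those where at least half the tracks
    (and no fewer than 2) contribute. Returns the pooled coverage fraction.
    """
    markers = [MarkerSpec("Erd1", 0.0, PULSE_WIDTH_S), MarkerSpec("Mnn9", 0.0, PULSE_WIDTH_S)]
    covered = total = 0
    used_sims = 0
    for i in range(n_sims):
        cfg = _movie_config(_seed_from(seed, 500 + i), n_puncta)
        movie, gt = simulate_maturation_movie(cfg, markers)
        report = analyze_movie(movie, reference_channel="Erd1")
        selected = report.selected
        if len(selected) < 2 or report.averaged is None:
            continue
        used_sims += 1
        avg = report.averaged
        width = PULSE_WIDTH_S
        pos = gt.puncta[["row", "col"]].to_numpy()
        true_peaks = gt.puncta["peak_time_Erd1"].to_numpy()
        truth_stack = np.full((len(selected), avg.times.size), np.nan)
        for k, tr in enumerate(selected):
            d = np.linalg.norm(pos - tr.positions[0], axis=1)
            t_true = true_peaks[int(np.argmin(d))]
            g_support = np.exp(-((tr.times - t_true) ** 2) / (2 * width**2))
            m, mx = g_support.min(), g_support.max()
            nt = normalize_track(tr)
            t_hat = peak_time(nt, "Erd1")
            aligned0, aligned1 = tr.times[0] - t_hat, tr.times[-1] - t_hat
            inside = (avg.times >= aligned0 - 1e-9) & (avg.times <= aligned1 + 1e-9)
            g = np.exp(-(((avg.times[inside] + t_hat) - t_true) ** 2) / (2 * width**2))
            truth_stack[k, inside] = (g - m) / (mx - m)
        truth_mean = np.nanmean(truth_stack, axis=0)
        interior = avg.n_per_timepoint >= max(2, int(np.ceil(avg.n_tracks / 2)))
        for ch in range(avg.mean.shape[0]):
            lo, hi = avg.ci_low[ch][interior], avg.ci_high[ch][interior]
            tv = truth_mean[interior]
            ok = (tv >= lo - 1e-9) & (tv <= hi + 1e-9)
            covered += int(ok.sum())
            total += int(ok.size)
    return {
        "n_sims": used_sims,
        "coverage_fraction": covered / total if total else float("nan"),
        "n_timepoints": total,
    }
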