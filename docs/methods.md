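# Methods

This note documents the models and procedures golgikin implements, the
parameters that matter, what the synthetic data do and do not emulate, and
the design choices made where the design was genuinely open.

## Image formation model (synthetic data)

A scene is built per frame and channel as

```
scene = (background + Σ_spots peak · G2D(σ_psf)) · illum
frame = Poisson(scene) + N(0, σ_read), hot pixels overwritten, clipped at 0
```

- **Spots.** Isotropic 2-D Gaussian, σ_psf = 1.5 px — the standard
  desk-scale approximation of a diffraction-limited punctum. The spot's
  *peak pixel value* equals the marker pulse value, so an isolated spot's
  integrated intensity is `peak · 2π σ_psf²` (held to <1% discretization
  error for σ_psf ≥ 1.5 px away from borders; verified by test).
- **Marker pulses.** Each punctum carries one temporal Gaussian pulse per
  marker: `a · exp(−(t − t_peak)²/2w²)`, width w = 10 s, amplitude
  a = 600 counts at peak. Real cisternal kinetics are not Gaussian; only
  unimodality and the peak time matter for every statistic computed here,
  and the Gaussian makes the truth analytic. Per-punctum reference peak
  times are drawn uniformly over the window that keeps every marker's
  peak ± 2w inside the movie; marker offsets are exact by construction.
- **Movies.** 2 s frame interval, 2 min duration (61 frames) — the
  acquisition regime of spinning-disk imaging of single compartments.
  Punctum positions are fixed over a movie (compartments that stay in the
  focal plane), with optional Brownian jitter (σ = 0.3 px/frame) to
  exercise the tracker.
- **Noise and artifacts.** Background 100 counts, Poisson shot noise,
  Gaussian read noise σ = 3 counts, hot pixels (salt impulses at 4000
  counts, redrawn each frame, default rate 1e-4), and a multiplicative
  illumination field (plane + Gaussian bump, spatial scale ≥ ¼ image
  width, relative amplitude 0.15) that a large-σ background subtraction
  can remove. No acquisition metadata (SNR, gain, amplitudes) exist for
  the real movies this emulates; these defaults give segmentable spots
  (peak SNR ≈ 15 over background) and are config-exposed rather than
  asserted as realistic.
- **Seeding.** One integer seed; geometry, pixel noise and hot pixels use
  independent child generators, so disabling one corruption leaves every
  other draw — and hence the rest of the image — bit-identical. This is
  what makes "same seed, hot pixels off" a valid per-pixel reference.
- **Cell images.** Cells are disks (radius 18 px) with a concentric
  vacuole disk (0.45 × cell radius); the cell's total flux (2e5 counts) is
  split between vacuole and cytoplasm at the designed fraction with uniform
  per-pixel density in each compartment. Masks are emitted as aligned label
  images, mirroring the workflow in which masks are drawn from DIC images
  and consumed by the quantification.

What the simulator does **not** emulate: 3-D/z-stacks, photobleaching,
cisternal fission/fusion, realistic cell morphology, or camera gain
structure. Passing recovery tests therefore demonstrates correctness of the
measurement chain under the stated forward model, not robustness to every
property of real data.

## Preprocessing

1. **Hot-pixel repair** (first, so impulses never leak into the background
   estimate). Selective median filter: residual = pixel − median(window×window
   neighborhood), window 3; robust spread = 1.4826 × MAD of the residuals. A
   pixel is replaced by its neighborhood median only when its residual
   exceeds k = 5 spreads **and** the pixel exceeds 3 × its neighborhood
   median (+ k spreads). The second, contrast condition is what
   distinguishes a sensor impulse (many-fold above any plausible local
   level) from a diffraction-limited spot peak, which exceeds its 3×3
   median by only ~20% of the spot amplitude: with the residual criterion
   alone, spot peaks get clipped on noisy images and *every* spot pixel on
   noise-free ones (where the MAD degenerates to 0). A plain median filter
   is not used because it erodes 2-px-scale puncta. Hot pixels on steep
   spot slopes are repaired only approximately (the neighborhood median
   differs from the true value there); in the sparse fields typical of
   this data (<0.4% of pixels under spots on a 512×512 frame) this affects
   a negligible fraction of impulses.
2. **Background subtraction.** `img − GaussianBlur(img, σ=10 px)`, clipped
   at 0. σ is ≫ σ_psf, so puncta lose <5% of their peak while camera offset
   and slow illumination gradients are removed; clipping keeps downstream
   Otsu on non-negative intensities.

## Segmentation

Otsu's threshold maximizes the between-class variance ω₀ω₁(μ₀−μ₁)².
Implementation detail fixed for bit-reproducibility: foreground is
*strictly above* the threshold and variance ties break toward the lower
threshold. When an image has ≤ n_bins (256) distinct values the search is
exact over those values (this is the regime of the brute-force oracle
tests); otherwise a 256-bin histogram is used and a bin edge returned.
Thresholds are computed per image and per channel, which is robust to
bleaching across a movie. Components are 8-connected; areas outside
[4, 200] px are rejected (single-pixel noise and vacuole-scale blobs — the
bounds are pipeline decisions, config-exposed). Centroids are
intensity-weighted. A constant image raises a degenerate-input error;
pipeline callers treat it as "nothing detected".

## Colocalization

Per query punctum, the intensity-weighted overlap ratio (fraction of the
punctum's signal inside the reference channel's mask) is the default — the
quantity plotted is colocalized *fluorescence* — with a pixel-count variant
behind a flag for sensitivity analysis. Ratios are pooled across images;
the summary is n, median, and a seeded percentile-bootstrap 95% CI of the
median (2000 resamples; the method behind the CI is a choice, as violin
annotations rarely name one). With 80% designed coincidence the pooled
*mean* tracks the coincident fraction (~0.8) while the *median* sits near 1
— the distribution is bimodal, which is exactly why such data are shown as
violins.

## Kinetics

- **Tracking** (the one stage with no manual counterpart: visual
  identification is replaced by an automatic linker). Detection runs per
  frame on the channel-sum image; greedy nearest-neighbor linking accepts
  closest pairs first, rejects links beyond 3 px, and bridges gaps up to 1
  frame by position hold. A detection frame is accepted only when its Otsu
  threshold exceeds the frame's robust noise floor (median + 5 × 1.4826 ×
  MAD): per-frame Otsu on a frame with no active compartment otherwise
  splits the noise into hundreds of spurious blobs. The floor is robust to
  the spots themselves (they occupy few pixels) — an sd-based floor was
  rejected because bright frames inflate it and valid detections drop out.
- **Trace extraction.** Per frame, integrated intensity in a 3 px-radius
  disk about the track position minus (local annulus median, radii 5..7) ×
  disk area, clipped at 0 — immune to residual uniform background. The
  measurement window extends 8 frames beyond the detected lifetime
  (position held): detection ends where the spot meets the threshold, i.e.
  at ~20–50% of peak, and without the extension a trace never samples its
  baseline, which breaks both normalization and the rise-and-fall
  selection below.
- **Selection.** Analyzable compartments are those whose detected lifetime
  is strictly inside the movie (no truncation at t = 0 or t = end), spans
  ≥ 5 frames, and whose traces rise and fall (first and last values < 50%
  of the maximum — per channel for two-channel movies; on the channel-sum
  trace for more channels, since with several staggered markers the
  earliest is already bright when the compartment first becomes
  detectable).
- **Peak timing.** Centered moving-average smoothing (window 3 frames; 1
  disables), then argmax with ties to the earliest frame; quadratic
  sub-frame refinement is available behind a flag but off by default —
  argmax is assumption-free and the frame interval already bounds the
  error at 2 s. Δt = peak(second) − peak(first); positive means the second
  channel peaks later (stated in every output header).
- **Averaging.** Each normalized trace is shifted so its reference-channel
  peak sits at t = 0 (the convention that places both peaks of a
  zero-offset pair on one dashed line), linearly interpolated onto a grid
  at the frame interval, and averaged per timepoint; the 95% CI is
  two-sided from the t-distribution over the tracks present at that
  timepoint, and timepoints with < 2 tracks are dropped. In the CI-coverage
  validation, "interior" timepoints are those where at least half the
  tracks (min 2) contribute, and the truth compared against is the
  analytic pulse normalized over each track's own observed support.
- **Ordering.** Markers are sorted by median Δt to a common reference;
  medians within one frame interval of a group's first member are reported
  as coincident. Conditions are imaged pairwise (reference + one marker
  per movie), matching two-color acquisition.

## Vacuolar quantification

Background is the median intensity outside all cell masks — a robust
estimate that stops camera offset from biasing ratios (whether the original
sums were background-corrected is unstated; this subtraction is a declared
choice). Corrected intensity is clipped at 0; the per-cell percentage is
100 × vacuole sum / cell sum; vacuole pixels outside the cell are dropped
with a warning. Replicates are aggregated as mean of per-cell percentages
per replicate, then grand mean and SD across replicate means (equal weight
per experiment); a single replicate reports SD 0 with a flag.

## Problem sizes used in validation

Chosen to match the statistics the readouts are quoted at: colocalization
pools 250 query puncta (5 fields × 50); kinetics movies carry 16–24
compartments per condition (>15 analyzable tracks each); ordering recovery
runs 20 seeded replicates × 4 pairwise movies; vacuolar recovery uses 3
replicates × 25 cells; CI coverage averages ~10 tracks per movie over 100
seeded simulations (60 in the acceptance script, recorded in its output).
Movies are 160×160 px; snapshot and cell fields 256–512 px square
(sensor-scale frames).

## Known limitations

- Greedy nearest-neighbor linking has no motion model; it is adequate for
  near-stationary compartments but not for fast or crossing trajectories.
- Touching puncta merge (no watershed splitting); sub-pixel localization is
  centroid-based, not PSF-fitted.
- Min–max normalization makes trace tails sensitive to the single minimum
  sample; the annulus subtraction and baseline padding mitigate but do not
  remove this.
- Otsu assumes a foreground that meaningfully shifts the histogram; in
  extremely sparse fields (foreground ≪ 0.1% of pixels) the threshold can
  drift into the noise — the tracking noise-floor guard handles this for
  movies, but single-snapshot segmentation of near-empty images should be
  sanity-checked.
- The vacuole/cell masks are trusted inputs; mask errors propagate directly
  into the percentages.
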