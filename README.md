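# golgikin

Quantitative analysis of Golgi marker puncta in yeast fluorescence
microscopy: object-based colocalization, single-compartment maturation
kinetics with peak-to-peak marker timing, and vacuolar mislocalization —
validated end to end against a synthetic movie generator with known ground
truth.

## The problem

In budding yeast the Golgi is a collection of individual cisternae that
appear as diffraction-limited puncta. Under the cisternal-maturation model a
cisterna changes identity over ~1–2 minutes from *early* (Mnn9) through
*medial* (Gea2) to *late* (Sec7), and resident proteins recycle backward.
Three quantitative readouts characterize where a protein of interest (e.g.
Erd1, Vps74, COPI) acts in this cycle:

1. **Object-based colocalization.** Puncta are segmented per channel (Otsu
   threshold, 8-connected components, size filter) and each query punctum is
   scored by the fraction of its fluorescence lying inside the other
   channel's mask:
   `r = Σ_{p ∈ punctum ∩ maskB} I_A(p) / Σ_{p ∈ punctum} I_A(p) ∈ [0, 1]`,
   pooled over ~250 puncta and summarized as median with bootstrap 95% CI.
2. **Peak-to-peak kinetics.** In two-color time-lapse movies (2 s frames,
   2 min) single compartments are tracked, per-channel intensity traces are
   min–max normalized to [0, 1], and the signed offset
   `Δt = t_peak(channel 2) − t_peak(channel 1)` is computed per compartment
   (positive = the second marker peaks later). Medians of Δt against a
   common reference marker order the markers on the maturation timeline;
   peak-aligned averaged traces with t-distribution 95% CIs show the pulse
   shape.
3. **Vacuolar mislocalization.** Per cell, with cell and vacuole masks as
   inputs, `100 × Σ(I − bg)⁺_vacuole / Σ(I − bg)⁺_cell` where bg is the
   median intensity outside all cells; means per replicate, then the grand
   mean ± SD across ~3 replicates of ~25 cells.

Before quantification every frame is corrected for hot pixels (selective
median repair) and uneven illumination (large-σ Gaussian background
subtraction).

Because no raw data accompany such analyses, the package ships a
synthetic-data module that generates movies, colocalization fields, and
whole-cell images with full ground truth (true positions, true peak times,
true coincidence, true vacuolar fractions), and every stage is validated by
recovering designed truth.

## Worked example

```sh
python analysis/04_marker_ordering.py --seed 1
```

simulates one two-channel movie per marker pair (reference Mnn9 plus one of
Erd1/COPI/Vps74/Sec7 at designed offsets 0/+6/+12/+20 s), runs the full
pipeline on each, and prints:

```
Mnn9 -> Erd1: designed +0 s, recovered median +0.0 s (n=24)
Mnn9 -> COPI: designed +6 s, recovered median +6.0 s (n=24)
Mnn9 -> Vps74: designed +12 s, recovered median +12.0 s (n=24)
Mnn9 -> Sec7: designed +20 s, recovered median +20.0 s (n=24)
recovered order: Erd1 ~ Mnn9 < COPI < Vps74 < Sec7
```

Each line is the median signed peak-to-peak time over the analyzable tracks
of that pair's movie; the last line groups markers whose medians lie within
one frame interval (2 s) as coincident and orders the rest. The other
drivers follow the same pattern: `analysis/01_colocalization.py` (250-punctum
overlap pool: mean 0.781 against a designed coincident fraction of 0.8),
`analysis/02_vacuolar_mislocalization.py` (grand mean 39.96% against a
designed 40%), `analysis/03_maturation_kinetics.py` (zero-offset movie:
median Δt +0.0 s, peak-aligned averaged trace with CI band).

The same machinery is available as a CLI for your own TIFFs
(`golgikin simulate|preprocess|coloc|kinetics|vacratio|demo`, movies as
(T, C, Y, X) uint16 TIFF), and as a library (`golgikin.segmentation`,
`golgikin.colocalization`, `golgikin.kinetics`, `golgikin.vacuolar`,
`golgikin.synthetic`).

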