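# Methods

## Scope and model

`slidequant` reproduces, on synthetic data with exact ground truth, the
full measurement chain of a high-content whole-slide drug-biodistribution
assay: two-pass acquisition (survey → high-magnification re-scan),
illumination correction and montaging, nucleus/epithelium segmentation,
partition of the labeled-drug channel into specific (on nucleated
epithelial regions) versus non-specific signal, and the validation
statistics (IOU, tiled count R²). The package analyzes single-plane 2D
multichannel images; z-stacks, spectral bleed-through and instrument
control are out of scope.

## Synthetic tissue generator

The generator is first-class, tested code: it defines the study
conditions every quality figure is measured under.

**Geometry.** Crypts are elliptical annuli (lumen surrounded by an
epithelial ring). Default: 9 crypts of radius 30 ± 6 μm with a 12 μm
ring on a 1024×1024 px slide at 0.3 μm/px (a plausible pitch for a 20×
objective on a large CMOS sensor; survey images are produced by 4×
downsampling, matching the 20×/5× magnification ratio). Eccentricity
U(1.0, 1.3) and random orientation mimic the variability of sectioned
crypts. Placement uses a jittered grid with center spacing
2.2·(radius + thickness): deterministic for any seed and guaranteed
non-overlapping; a slide too small for the requested crypts raises a
degenerate-geometry error rather than silently under-placing.

**Nuclei.** Centers are drawn inside the epithelium at 0.8 nuclei per
100 μm² (and 0.05 per 100 μm² in the stroma) by greedy dart-throwing
with a minimum spacing of 1.9 nucleus radii, so densely packed nuclei
remain optically resolvable. Nuclei render as flat-topped discs with
soft (super-Gaussian) edges, radius 3.5 ± 0.5 μm.

**Drug channel.** The total slide drug budget follows a two-exponential
uptake/clearance surrogate

    B(t) = A · dose · (e^(−k_c t) − e^(−k_u t)) / (k_u − k_c),

defaults k_u = 0.5/h, k_c = 0.05/h (peak at ≈ 5.1 h, so the study's
2 h sample lies on the rise and 24/48 h on the clearance tail). The
kinetic form and all its constants are this package's own surrogate —
the source assay reports a time course but no kinetic model — and
should not be read as measured pharmacology. A fraction
`interstitial_fraction` (default 0.2) of B is deposited as Gaussian
blobs in the stroma (trapped, non-specific drug); the rest is painted
on 7 μm cell discs inside the epithelium with log-normal per-cell
uptake (σ_ln = 1.0), emulating heterogeneous biodistribution. Both maps
are renormalized exactly, so specific + interstitial = B(t) to
floating-point precision — the conservation identity the quantification
tests rely on.

**Intensity scale.** The amplitude A = 6·10⁷ (integrated intensity
units per slide) is arbitrary — the assay publishes no intensity
calibration — and is chosen so the per-pixel drug signal at every study
time point (≈ 140–1400 units) dominates the camera noise floor, the
regime in which the planted specific fraction is recoverable from the
degraded image within the package's stated ±0.1 tolerance. Weaker
staining degrades recovery gracefully (the clipped read-noise floor of
the glass area inflates the non-specific sum).

**Degradation.** Each channel is blurred (Gaussian, σ = 0.6 μm:
diffraction plus the mild defocus of imperfectly flat frozen sections),
multiplied by a per-FOV radial vignette 1 − s·(r/r_max)² (s = 0.3)
stamped across the slide on the FOV grid, then degraded by Poisson shot
noise (scale 0.5 counts/unit) and additive Gaussian read noise (σ = 4),
clipped at zero. Ground truth is kept pre-degradation. What the
generator does **not** emulate: real chromatin texture, stain
cross-talk, tissue folds, autofluorescence, and focus variation — so
passing quality bars here demonstrates correctness of the measurement
chain, not segmentation performance on real tissue.

## Acquisition emulation

The survey thresholds the low-resolution nuclear channel (Otsu),
keeps 8-connected components ≥ 500 px and returns their bounding boxes
scaled to the high-magnification frame. The pipeline driver first
smooths the survey image at crypt scale (6 low-res px) so individual
nuclei merge into tissue blobs; the `prescan_roi` operation itself
remains an exact threshold-and-label contract.

FOV plans are row-major grids with stride `round(size·(1−overlap))`
(overlap 0.10), the last row/column clamped to end exactly at the ROI
edge — every ROI pixel is covered for any overlap in [0, 1).

Flat-field correction is retrospective: the per-pixel median across
FOVs, smoothed (σ = FOV/8) and normalized to mean 1, approximates the
shared illumination profile when tile content is diverse; each FOV is
divided by it. A single FOV passes through unchanged (warned); a
degenerate zero median is floored at 10⁻⁶ of the field mean (warned).
Correction runs before stitching (the vendor ordering is unspecified;
this choice is fixed and documented here).

Stitching blends tiles with separable linear feather ramps over the
overlap margins, normalized per pixel; pixels covered by exactly one
tile reproduce that tile bit-exactly, so plan→crop→stitch is a strict
round trip on undegraded images.

## Segmentation

The default backend is deterministic and classical. Nuclei: maxima of
the scale-normalized negated Laplacian-of-Gaussian at σ = r/√2
(r = 3.5 μm, half the 7 μm whole-cell proxy), thresholded at 10% of the
global peak, greedily suppressed within 5 μm, ties broken by (row, col).
Epithelium: Gaussian smoothing (1.5 μm) → Otsu → remove objects
< 100 μm² → fill holes < 50 μm². The hole budget is deliberately far
below crypt-lumen area (~2800 μm²) so lumens survive as genuine holes.

The trainable backend is a small 2-level encoder–decoder with skip
connections (NumPy forward/backward, im2col convolutions, Adam),
optimizing the weighted soft-max cross-entropy

    L = Σ_p w_p · (−log softmax(s_p)[y_p]) / Σ_p w_p.

Defaults mirror the original fine-tuning protocol — learning rate 10⁻⁵,
6,000 iterations (epithelium) / 10,000 (nuclei) — and scale down for
desk-scale runs (the tests train 150–300 iterations at 10⁻³ on 64×64
tiles, reaching held-out IOU > 0.95 on two-level blob tiles in ~10 s on
one CPU). Per-pixel weights default to uniform; `border_weight_map`
provides a 3× emphasis within 3 px of label boundaries. Point
annotations are not converted to training targets by the package; the
tests rasterize discs themselves (radius ~3 px is a reasonable choice).
Model state serializes to one `.npz` with an embedded format-version
tag and reloads to bit-identical inference.

## Quantification

Nucleated cell proxies are Euclidean discs (inclusive radius, default
7 μm) around each center, merged by union and clipped at borders;
intersection with the epithelium mask gives the nucleated epithelial
regions (8-connectivity throughout). Drug partition is an exact sum
split, so specific + nonspecific equals the image total to accumulator
precision. Region densities are per-region integrated drug divided by
region area in μm² (per-pixel histograms were considered and rejected
as the default: the histogram counts then depend on pixel pitch rather
than biology; a per-pixel variant can be built from the region table).

**Occupancy** has no published numeric definition; this package defines
it as the fraction of nucleated-epithelial *pixels* whose drug signal
exceeds τ = mean + 3σ of a tissue-free background context (glass
outside the pre-scan ROI — the only principled reference available
without a published threshold; `fixed` thresholds and a per-*region*
variant are available behind flags). Comparisons across packages should
treat occupancy values as internally consistent, not as the original
assay's axis.

## Validation statistics

IOU is the exact set ratio |∩|/|∪| (undefined and signalled when both
masks are empty). The tiled count comparison grids a region into
⌊h/t⌋×⌊w/t⌋ *full* square tiles of 104 μm (half-open, so boundary
points belong to exactly one tile; partial edge tiles are dropped —
a 416×416 μm region yields exactly the reference 4×4 = 16 squares).
R² is the squared Pearson correlation of the paired counts; for a
simple linear fit this coincides with regression R², so either reading
of "calculate R²" is honored.

## Problem sizes and determinism

Default-condition figures are computed on one 1024×1024 px slide
(~0.31×0.31 mm of tissue, ~230 nuclei) and a 448×448 px validation
image at 1 μm/px for the count correlation; the package's own test
suite completes in well under a minute on one CPU at these sizes.
Every stochastic component draws from `numpy` generators spawned from a
single integer seed; identical parameters give bit-identical slides,
and the pipeline writes byte-identical CSV outputs on repeated runs.

## Known limitations

- The classical baseline is tuned to the synthetic phenotype; real
  tissue would favor the trainable backend with real annotations.
- The PK surrogate, intensity amplitude and background model are
  package choices, not measured values; occupancy magnitudes are not
  comparable to the original assay.
- Flat-field estimation assumes diverse tile content; slides dominated
  by one texture bias the median field.
- Stage-position error registration is not modeled: plans are exact by
  construction, so stitching never needs cross-correlation alignment.
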