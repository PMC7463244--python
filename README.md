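# slidequant

Whole-slide fluorescence quantification of drug biodistribution in gut
tissue, for imaging scientists and DMPK groups who need cell-resolved
answers to "how much of the labeled drug is bound where it should be?"

A fluorescently labeled antibody (e.g. an anti-cadherin-17 conjugate)
is dosed to mice; colon and small-intestine sections are counterstained
with DAPI (nuclei) and anti-EpCAM (epithelium) and imaged on a
high-content confocal reader in two passes: a fast low-magnification
survey of the nuclear channel finds the tissue, and the region of
interest is re-imaged at high magnification as a grid of fields of view
with 10% overlap, flat-field corrected and montaged. Analysis then

1. detects nuclei in the DAPI channel and segments the epithelium in
   the EpCAM channel,
2. dilates each nucleus by r = 7 μm (a whole-cell proxy) and intersects
   with the epithelium mask to form **nucleated epithelial regions**,
3. partitions the drug channel D over the region mask M:

       specific   = Σ_{p ∈ M} D(p)        (on-target binding)
       nonspecific = Σ_{p ∉ M} D(p)       (incl. interstitial trapping)

4. reports per-region densities (intensity/μm²) as a histogram and an
   **occupancy** — the fraction of nucleated-epithelial area whose drug
   signal exceeds background (mean + 3σ of tissue-free glass) — over
   the sampling time course (2, 24, 48 h after a 3 mg/kg dose).

Segmentation quality is validated with Intersection-Over-Union
(IOU = |A∩B| / |A∪B|; ≥ 0.8 is the customary high-quality bar) and
nucleus detection by the squared Pearson correlation R² of paired
counts over square tiles 104 μm across.

No imaging data ship with the package: a seeded synthetic-tissue
generator renders crypt-shaped epithelial rings, intra-epithelial and
stromal nuclei, and a pharmacokinetically scaled drug channel with
per-FOV vignetting, blur and shot/read noise — together with exact
ground truth, so every stage can be scored quantitatively. See
`docs/methods.md` for the model details.

## Worked example

```python
import slidequant as sq
from slidequant.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(synth=sq.SynthParams(time_h=24.0), seed=1,
                     outdir="example_out")
manifest = run_pipeline(cfg)
print(manifest.results)
```

prints (one 1024×1024 px slide at 0.3 μm/px, 24 h time point):

```
n_roi_boxes            9          # tissue blobs found by the pre-scan
n_tiles                25         # planned 256px FOVs at 10% overlap
n_nuclei               232        # detected by the LoG baseline
epithelium_area_um2    25077.51
specific_total         7.965e+07  # drug intensity on nucleated epithelium
nonspecific_total      2.899e+07  # interstitial + stray signal
occupancy              0.962      # above-background fraction of that area
iou                    0.929      # epithelium mask vs ground truth
r_squared              0.9998     # detected vs planted counts per 104-μm tile
```

The specific fraction 0.73 ≈ the planted 0.80 (optical blur moves some
signal across region borders); IOU 0.93 clears the 0.8 quality bar, and
the count correlation far exceeds the 0.70 reference. The same stages
are available individually from the `slidequant` CLI (`simulate`,
`prescan`, `plan`, `correct`, `stitch`, `segment`, `quantify`,
`evaluate`, `pipeline`).

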