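# Methods

## The MT-DTE score

MT-DTE (microtubule drug-target engagement) quantifies taxane-induced
microtubule bundling in a single cell from the tubulin channel of a
multichannel confocal z-stack.  The operational definition is
intentionally simple and per-image:

* the tubulin maximum-intensity projection is exported to 8 bits;
* the threshold is dynamic — upper bound the image maximum `M`, lower
  bound `0.75·M` — so the ROI is the top 25% of the image's own intensity
  range, and the score needs no cross-cell intensity calibration;
* the score is the ROI's integrated density, `mean × area`, identically
  the summed ROI pixel intensity.

Assumptions this encodes: imaging conditions are constant within a sample
set (the threshold adapts per cell, but relative bundling brightness is
what carries signal); bundles manifest as a heavy upper tail of the
intensity histogram; ROI topology is irrelevant (no connectivity
filtering, no minimum object size — the ROI is the raw super-threshold
pixel set).

Numerical choices:

* **Boundary rule.** `v ≥ 0.75·M` is inclusive, and the comparison is done
  in real arithmetic — for integer images the lower bound is *not*
  rounded, so with `M = 255` a 191 pixel is excluded and 192 included.
  The arg-max pixel always satisfies the threshold, so the ROI is never
  empty.
* **Value-based, not rank-based.** "Top 25%" refers to the intensity
  range (`≥ 75% of max`), not to the top quartile of the pixel-count
  distribution.  A rank-based variant is deliberately not provided.
* **Degenerate images.** An all-zero projection raises
  `DegenerateImageError` and the cell is reported as a missing score.
  Scoring it 0 would silently drag down timepoint means.
* **8-bit conversion.** Default mode `scale_zero_max` maps `[0, max]`
  linearly onto `[0, 255]` with round-half-up.  Under this mode the ROI
  mask is invariant to the conversion (the threshold is relative to the
  maximum), which is why it is the default; `scale_minmax` and
  `truncate` are available for sensitivity analysis.  ROI statistics are
  computed *after* conversion, matching the stated export order.
* **Reported scale.** Raw integrated density is reported, with an
  explicit `scale_factor` multiplier (default 1) recorded in the output.
  No hidden normalization is applied; the absolute scale of published
  MT-DTE values is not derivable from their operational definition, so
  any rescaling must be an explicit user choice.
* **Integer exactness.** The integrated density is accumulated as an
  exact float64 sum of the masked pixels, so integer inputs are scored
  exactly (verified against a brute-force oracle).

## CTC identification

Nuclear segmentation is the simplest defensible chain for well-separated
cytospun cells: Gaussian smoothing (σ = 1 px) of the DAPI channel, Otsu
threshold (floored at background median + 6·MAD so empty fields yield no
detections), hole filling, erosion by a radius-2 disk, connected
components, and a minimum-size filter.  The erosion cuts the thin bridges
that soft nuclear edges form between adjacent nuclei, so touching cells
separate without watershed (which is out of scope); substantially
overlapping nuclei still merge and are flagged (`merged_candidate`)
rather than split.  Measurements are taken over the eroded nucleus core —
which also reduces edge contamination of the per-channel means — and the
equivalent diameter is compensated by twice the erosion radius.

Gating implements the standard CTC phenotype: DAPI+, CK+ (epithelial),
CD45− (not a leukocyte), plus TUB+ (scoreable) and AR+ (prostate
lineage), with morphology filters.  Positivity is `channel mean ≥
threshold` (inclusive).  Default thresholds are estimated per channel as
`k·(median + 3·MAD)` of the tile (k = 3); fixtures use absolute
thresholds for exactness.  Morphology defaults — equivalent diameter
8–30 µm (of the nuclear component), circularity ≥ 0.5 — are configuration
values, not assay constants.  DAPI+/CD45+ objects are recorded as
leukocytes; everything else failing the CTC conjunction is rejected.
Putative CTCs are ranked by CK mean (descending, ties broken by cell id)
and capped at 20 per patient × timepoint, interpreted as a hard cap after
gating (gate-then-rank).  Manual operator confirmation of the real assay
is replaced by centroid matching against synthetic ground truth within
one true cell radius.

## The synthetic generator

The generator emulates the statistical structure the analysis depends
on, not the physics of the instrument:

* **Tile scans** (10×-like, 1 µm/px default): soft-edged disks for cell
  bodies and nuclei; CTCs (16 µm, CK 15 000 ≫ CD45 250), leukocytes
  (10 µm, CD45 12 000 ≫ CK 250) and small DAPI-dim debris (4 µm), placed
  by rejection sampling with at most 5% radial overlap; per-cell levels
  drawn with channel-specific coefficients of variation.
* **Single-cell stacks** (0.3 µm/px, 20 z-slices at 0.24 µm): tubulin is
  a diffuse textured component plus `ceil(8·b)` anisotropic Gaussian
  ridges for bundling level `b ∈ [0, 1]` — random position/orientation,
  length of order the cell diameter, width and amplitude growing with
  `b`.  Ridges are composited with a per-voxel **maximum** (against each
  other and the diffuse component): additive compositing would create
  doubled-intensity hot spots at filament crossings that capture the
  dynamic threshold and break the intended monotone dose–response.  The
  diffuse texture is a low-pass-filtered uniform field cubed, so a
  purely diffuse cell keeps a small super-threshold ROI.  Expected
  MT-DTE is strictly increasing in `b` (measured means ≈ 14k, 29k, 62k,
  98k, 133k over b = 0, 0.25, 0.5, 0.75, 1).
* **Noise**: additive Gaussian read noise (default SD = 2% of the CTC CK
  mean) plus optional Poisson shot noise.  Intensities are generated in
  the 16-bit range so the 8-bit export path is always exercised.
* **Cohorts**: patients × timepoints (labels C1D1 … C2D8), per-timepoint
  CTC counts Poisson with the designed expectation (a fixed-count mode
  exists for benchmarks), bundling levels `N(mean, sd)` clipped to
  [0, 1].  Responder profiles have week-1 (C1D8/C2D8) bundling means
  strictly above their cycle baselines; stable profiles do not.
  Not-received samples are a first-class status.  Identical
  (design, seed) produce byte-identical manifests.

What the generator does **not** emulate: optics (no PSF, no
depth-dependent blur), staining chemistry, autofluorescence, cell-shape
irregularity, imaging-condition drift, or biophysical microtubule
structure.  Passing tests therefore demonstrate that the *pipeline*
recovers known structure under its stated assumptions — not that the
assay performs at these levels on real specimens.

### Calibration of the responder benchmark

The recovery benchmark asks whether the baseline→week-1 contrast flags a
true responder.  The effect size is expressed in units of per-cell score
noise: with baseline bundling `N(0.15, 0.08)` the per-cell score SD is
≈ 9.5 × 10³ (300 cells); a week-1 bundling mean of 0.25 shifts the mean
score by ≈ 1.16 of those SDs.  These values are frozen as the default
responder design.  With 10 cells per timepoint the standard error of a
mean difference is `SD·√(2/10) ≈ 0.45 SD`, so a ~1.2 SD effect is
recovered per cycle with probability ≈ 0.99, and both cycles jointly in
≈ 98–99% of replicates; stable patients sit at chance (~50% of contrasts
positive).

## Aggregation

Per-timepoint statistics are the arithmetic mean and the sample SD (n−1
denominator; undefined and reported missing for n = 1).  The mean is
computed in exact rational arithmetic (`fractions.Fraction`) and rounded
once to float64: a conventional sum-then-divide mean is order-dependent
and can land one ulp away from the true mean — for some (n, mean)
combinations *no* float64 division even reaches the true value — whereas
the correctly rounded mean is permutation-invariant and reproduces
printed tables digit for digit.  SDs use the conventional float path
(no printed-value reproduction depends on them).

Longitudinal contrasts compare each cycle's baseline with its week-1
draw (C1D1↔C1D8, C2D1↔C2D8).  The 4-hour and 24-hour timepoints are
summarized but never enter the contrast: early engagement reflects
initial drug binding rather than sustained target engagement.  A missing
side (sample not received, or no analyzable cells) yields a missing
`increased` flag, never `False`, and missing data are never imputed.  No
hypothesis tests are computed — at reference-cohort scale (three
patients) the contrasts are descriptive.

## Problem sizes

Default benchmark sizes are chosen to characterize the pipeline well at
desk scale: 1000 random images for the scoring oracle, 30 cells per
bundling level for the dose–response grid, 100 replicate cohorts × 2
patients × 4 timepoints × 10 cells for responder recovery, and a 220-cell
tile (40 CTC / 170 leukocyte / 10 debris) for the gating benchmark.

## Known limitations

* Segmentation has no watershed: heavily overlapping nuclei are flagged,
  not resolved, and their channel means are mixtures.
* The filament model is phenomenological; scores on synthetic cells are
  comparable across bundling levels but not to any real instrument's
  absolute values.
* Background-derived gate thresholds assume cells are sparse in the
  tile; dense fields bias the median/MAD estimate upward.
* The absolute scale of published MT-DTE values cannot be reproduced
  from their operational definition; only an explicit `scale_factor` is
  offered.
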