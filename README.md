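# ctcdte

Quantification of **microtubule drug-target engagement (MT-DTE)** in
circulating tumor cells (CTCs) from multiplex fluorescence microscopy.

Taxanes (docetaxel, cabazitaxel and nanoparticle conjugates such as
CRXL301) act by binding and stabilizing microtubules; successful target
engagement reorganizes the tubulin network into thick, bright bundles.
Because CTCs can be sampled repeatedly from peripheral blood, bundling in
CTCs is a candidate pharmacodynamic biomarker: a rise in MT-DTE one week
after dosing, relative to the cycle baseline, tracks clinical response,
while the strong engagement seen within 4–24 h of dosing does not.  This
package is aimed at researchers analyzing such liquid-biopsy imaging
assays — and, because no raw patient imagery is publicly available for
this assay, at anyone who needs a fully synthetic, ground-truthed
test bed for the analysis.

## The score

For a single cell imaged as a confocal z-stack (5 channels: DAPI, pan-CK,
CD45, tubulin, AR; ~20–40 slices at 0.24 µm), the MT-DTE score is computed
from the tubulin channel:

1. **Maximum-intensity projection** over z:  `P(y,x) = max_z I(z,y,x)`.
2. **8-bit export**: `v → round(v·255 / max P)` (the conversion under which
   the threshold mask below is invariant; alternatives are configurable).
3. **Dynamic threshold**: upper bound `M = max(P)`, lower bound `0.75·M`;
   the region of interest (ROI) is the raw pixel set `{v : v ≥ 0.75·M}`
   (inclusive, compared in real arithmetic — the top 25% of the image's own
   dynamic range).
4. **Integrated density**: `MT-DTE = mean(ROI) × area(ROI) = Σ_{ROI} v`.

An all-zero projection has no defined score and is reported as *missing*,
never 0.  Cells are found in low-resolution tile scans by minimal nuclear
segmentation (Otsu on DAPI, hole filling, erosion-based component
separation, size filter) and gated as putative CTCs by the standard
DAPI+/CK+/CD45− phenotype plus tubulin and AR positivity; confirmed CTCs
are ranked by CK intensity and at most 20 per patient × timepoint are
scored.  Per-cell scores are aggregated into per-patient × timepoint
means (sample SD, n−1), and baseline-vs-week-1 contrasts (C1D1↔C1D8,
C2D1↔C2D8) flag whether engagement increased.

## Worked example

```python
from ctcdte import ctc_phenotype, render_cell_stack, score_ctc

diffuse, _ = render_cell_stack(ctc_phenotype(bundling_level=0.1), seed=1)
bundled, _ = render_cell_stack(ctc_phenotype(bundling_level=0.8), seed=1)
for name, stack in [("diffuse", diffuse), ("bundled", bundled)]:
    s = score_ctc(stack, cell_id=name)
    print(f"{name}: threshold [{s.bounds.lower:.2f}, {s.bounds.upper:.0f}], "
          f"ROI {s.roi_area_px} px, mean {s.roi_mean_intensity:.1f}, "
          f"MT-DTE {s.integrated_density:.0f}")
```

prints

```
diffuse: threshold [191.25, 255], ROI 58 px, mean 224.7, MT-DTE 13034
bundled: threshold [191.25, 255], ROI 498 px, mean 220.4, MT-DTE 109765
```

Both cells are thresholded at 75% of their own 8-bit maximum (191.25), so
the score difference is driven by how much of the cell sits in the bright
upper tail: the bundled cell's filaments put ~9× more pixels into the ROI,
and its integrated density is ~8× higher.  Aggregation over the bundled
reference cohort:

```python
from ctcdte.cohort_analysis import (reference_summaries, summarize_counts,
                                    total_confirmed_ctcs, longitudinal_contrasts)

summaries = reference_summaries()
print("total confirmed CTCs:", total_confirmed_ctcs(summaries))
p1 = [s for s in summaries if s.patient_id == "Patient 1"]
cs = summarize_counts(p1)
print(f"Patient 1 counts: mean {cs.mean_count:.0f}, range {cs.min_count}-{cs.max_count}")
for c in longitudinal_contrasts(p1):
    print(f"cycle {c.cycle}: {c.baseline_timepoint} {c.baseline_mean} -> "
          f"{c.week1_timepoint} {c.week1_mean} (increased: {c.increased})")
```

```
total confirmed CTCs: 149
Patient 1 counts: mean 6, range 1-17
cycle 1: C1D1 0.19 -> C1D8 1.0 (increased: True)
cycle 2: C2D1 0.17 -> C2D8 0.45 (increased: True)
```

Patient 1 — the responder in the reference cohort — shows the week-1
MT-DTE increase in both treatment cycles.

## Command line

```bash
ctcdte simulate  --out cohort/ --seed 0          # synthetic labeled cohort
ctcdte detect    --tile cohort/P1/C1D1/tile.tif --out objects.csv
ctcdte score     --input cohort/ --out scores.csv
ctcdte summarize --scores scores.csv --out report/
ctcdte run-all   --out run/ --seed 0             # all of the above
```

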