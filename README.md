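# mrdqc

Batch quality-control toolkit for **processed** multimodal brain-MRI
studies. After a research pipeline has co-registered, skull-stripped,
intensity-normalized, and automatically segmented a cohort, someone still
has to look at the results: registrations slip, brain masks clip cortex,
tumor segmentations fail, normalization breaks. `mrdqc` supports that
review at scale for imaging scientists and physicists curating datasets
for radiomics or deep-learning work:

* **Snapshot rendering** — for every study, a fixed set of static PNG
  panels is pre-rendered once: three-plane overlays of each annotation
  (brain mask, three-label tumor segmentation, CSF ROI) at the slice with
  the **maximum segmentation area**, per-modality views with the brain
  mask contour at *identical* slice indices so misregistration is visually
  obvious, CSF-ROI confirmation panels, unit-peak ("scaled") intensity
  density plots per segmented region with the expected normalized range
  (default [-5, 5]) marked, and crosshair panels at the maximum-intensity
  voxel inside the tumor ROI for functional maps. Reviewing a handful of
  key slices trades free scrolling for throughput.
* **Automatic QC pre-flags** — robust (0.5th/99.5th percentile)
  within-brain intensity range vs. the expected normalized range, the
  fraction of tumor segmentation outside the brain mask (cropped
  field-of-view signature), and segmented tumor volumes in cm³. These are
  advisory; the quality calls are human.
* **Structured review log** — a CSV-backed schema with a three-level
  quality call (acceptable / poor / fail) per annotation category plus
  study-level flags (study artifact, image unusable, bias field,
  normalization failure, no PNGs, needs review). Logs merge
  deterministically (latest review of each study wins) and aggregate into
  a review-result table: per-category counts, failure rates, a combined
  per-study class (max severity), and tumor-volume RMSE against reference
  measurements stratified by segmentation quality,
  `RMSE = sqrt(mean((V_seg − V_ref)²))`.
* **Static HTML gallery** — a serverless index + per-case pages assembled
  from the pre-rendered panels; open `index.html` from the filesystem.
* **Synthetic phantom cohorts** — geometric brain/tumor phantoms with
  realistic multimodal contrast and six injectable failure modes
  (misregistration, bias field, normalization break, cropped FOV,
  corrupted segmentation, missing file), so the whole pipeline is testable
  with no imaging data on hand.

## Worked example

Generate a 20-study synthetic cohort with two failure modes, render and
screen it, and aggregate an oracle review:

```sh
mrdqc simulate cohort -n 20 --rates corrupt_seg=0.2,normalization_break=0.1 --seed 7 -o cohort
mrdqc render --manifest cohort/manifest.csv --out snaps
mrdqc qc --manifest cohort/manifest.csv --snapshots snaps --out qc.csv
mrdqc report build --manifest cohort/manifest.csv --snapshots snaps --log reviews.csv -o site
mrdqc review summarize reviews.csv --table1
```

The summarize step prints (for this seed, which injected 4 corrupted
segmentations and 1 normalization break):

```
n = 20
acceptable fraction: 75.0% (75%)
                    acceptable  minor_errors  failure
image_quality             20.0           NaN      0.0
normalization             19.0           NaN      1.0
brain_mask                20.0           0.0      0.0
registration              20.0           0.0      0.0
tumor_segmentation        16.0           0.0      4.0
csf_localization          20.0           0.0      0.0
review_result             15.0           0.0      5.0
```

15 of 20 studies pass review outright; the combined failure rate is 25%
(each injected failure fails exactly one category — the two-level rows
image quality and normalization have no "minor" tier). Stratifying the
segmented-vs-reference total tumor volume error by segmentation quality:

```
             n  rmse_cm3
acceptable  16      5.28
poor         0       NaN
fail         4    107.72
```

Acceptable segmentations disagree with the reference volumes only by the
reference noise (~5 cm³ here), while the corrupted segmentations are off
by >100 cm³ — data review is what keeps those out of downstream analysis.

Python API mirrors the CLI: `mrdqc.render_study`, `mrdqc.compute_study_qc`,
`mrdqc.summarize`, `mrdqc.rmse_by_quality`, `mrdqc.make_cohort`, etc.

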