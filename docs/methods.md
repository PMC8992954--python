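# Methods

## The review problem

Quantitative MR studies of brain tumors rest on a processed data product:
four co-registered anatomical modalities (T1, T1 with contrast, T2,
FLAIR), a brain mask from skull stripping, an automatic three-label tumor
segmentation (enhancing tumor, necrosis, edema), a CSF region of interest,
and z-score-like intensity normalization. Any of these steps can fail
silently, and raw-image QC tools do not look at the derived products.
`mrdqc` implements a *batch* review workflow: all informative slices are
rendered once as static rasters, a human records structured quality calls
in a CSV log, and the log is aggregated into failure rates and volume-error
summaries. The toolkit never computes registrations, masks, or
normalizations itself — it reviews their outputs.

## Geometric conventions

All volumes are reoriented to canonical RAS+ (axis 0 → Right, 1 →
Anterior, 2 → Superior) on load; the reorientation permutes/flips axes and
updates the affine so every voxel keeps its world position. Affines whose
voxel axes lie more than 45° from every cardinal direction are rejected as
oblique rather than silently mis-labelled. Anatomical planes are then
axial = axis 2, sagittal = axis 0, coronal = axis 1. Panels are drawn in
radiological style: axial and coronal images put the patient's left on the
viewer's right; superior (or anterior, for axial) is at the top. Voxel
volume is |det| of the affine's upper-left 3×3, so label volumes in cm³
are rotation-invariant.

Degenerate inputs are handled to keep the pipeline moving (its purpose is
to *surface* bad data): NaN voxels are replaced by the image minimum with
a warning, non-integer label values are rounded with a warning, and a
missing input file yields panels with status `skipped_missing_input` —
feeding the "No PNGs" review flag — never an aborted study.

## Slice selection and panel composition

The slice shown for a segmentation overlay is the one with the maximum
in-plane foreground area (ties → lowest index; empty map → middle slice).
Registration-check panels deliberately reuse the *brain mask's* max-area
slice indices on every modality: on co-registered data the yellow mask
contour hugs the brain on all four images, while a rotated modality
visibly disagrees. Display windowing is the 1st–99th percentile of
within-brain voxels per slice (whole slice when no mask is available) —
robust to the hot artifact voxels the panels exist to reveal. Overlays use
a fixed color-blind-aware palette (mask = yellow 1-pixel contour so the
anatomy underneath stays visible; tumor labels red/green/blue by ascending
label; CSF cyan) at alpha 0.4, later overlays drawn over earlier ones.

Density panels histogram the in-mask intensities of each segmented region
(100 bins over the pooled range) and rescale each curve to unit **peak**;
unit-area scaling would make small regions invisible next to the brain
curve, and peak scaling keeps curve *shapes* comparable, which is what the
range check needs. Dashed lines mark the expected normalized range
endpoints (default [-5, 5]). Crosshair panels mark the maximum-intensity
voxel inside the tumor ROI (ties → lexicographically smallest index;
empty ROI → image center) to show whether extreme functional-map values
are artifact or biology.

Rendering is deterministic: overlay panels are pure numpy → PNG, and the
matplotlib panels are written without date/software metadata, so
re-rendering a study is byte-identical.

## Automatic QC

Three advisory quantities are computed per study; they are surfaced next
to the panels and never auto-populate the human review:

* **Normalization check.** Robust within-brain range = 0.5th/99.5th
  percentiles of in-mask intensities; flagged iff it escapes the expected
  interval (default [-5, 5]). Percentiles rather than min/max: isolated
  hot voxels raise suspicion visually but should not trip a wholesale
  normalization flag.
* **Segmentation outside brain** = fraction of tumor-foreground voxels on
  brain-mask background (0 for an empty segmentation) — the signature of
  an excessively cropped field of view.
* **Tumor volumes**: total over all nonzero labels (the T2-FLAIR
  hyperintensity footprint) and the enhancing label alone; an absent
  "enhancing" role reports the volume as absent, not zero.

No automated misregistration score is computed; registration is checked
visually via the shared-slice mask overlay.

## Review log and aggregation

One review = three-level calls (acceptable/poor/fail) for brain mask,
tumor segmentation, CSF ROI, and registration, six boolean flags, a
free-form CSF-location string, a comment, reviewer, and a UTC timestamp.
"Poor" means minor errors unlikely to affect downstream processing;
"fail" means unusable. The CSV is the single source of truth; merging two
logs keeps, per study, the entry with the later timestamp (ties broken by
reviewer then serialized content, so merge is deterministic and
idempotent).

The combined per-study class is the maximum severity across inputs:
**failure** if any category failed or study-artifact / image-unusable /
normalization-failure is flagged; else **minor errors** if any category is
poor or bias-field is flagged; else **acceptable**. The bias-field flag's
severity is configurable (default minor) since a visible bias field may or
may not corrupt downstream values. The no-PNGs and needs-review flags gate
completeness, not quality, and do not enter the class. This rule is
monotone: worsening any one category never improves the combined class.

Aggregation produces the standard review-result table: three-level counts
per annotation category, two-level (no minor tier) rows for raw image
quality (artifact or unusable flags) and normalization, and the combined
row; failure rate = failures/n, acceptable fraction = (acceptable +
minor)/n, reported at one decimal and at the nearest integer. Volume RMSE
is stratified by the *tumor-segmentation* call (not the combined class),
restricted to studies whose image quality, registration, and brain mask
are all clean so that segmentation quality is the deciding factor; empty
strata report n = 0 with RMSE absent.

## Synthetic phantom cohort

The generator emulates what a processed study looks like to the reviewer,
not MR physics. Defaults: 64³ grid at 3 mm isotropic spacing (192 mm
field of view); an ellipsoidal brain (semi-axes 78/90/66 mm); spherical
tumor compartments (edema 27 mm, enhancing 18 mm, necrosis 9 mm radius)
offset from center so the cropped-FOV mode intersects the tumor; a 7.5 mm
CSF sphere. Per-tissue raw means encode the canonical contrast (enhancing
bright on T1C, edema bright on T2/FLAIR, CSF bright on T2 and suppressed
on FLAIR); Gaussian noise with sd 0.2 relative to unit tissue contrast
(≈ SNR 5) keeps a correctly normalized study's robust in-brain range
inside [-5, 5], as a clean study's should be; intensities are z-scored
within the brain mask. Every draw derives from the study seed, and
regeneration is byte-identical. A truth JSON records label voxel counts
and applied parameters.

Failure modes each degrade exactly one artifact and map to exactly one
review category: rotation of one modality about the axial axis (default
10°, linear resampling on the same grid) → registration; a smooth
multiplicative ramp (default amplitude 0.4) → bias field; a ×100
intensity scale → normalization; zeroing the top 30% of axial slices of
all images *and the brain mask* while leaving the tumor map intact (so
the segmentation exits the brain) → image quality; dilating (2 voxels)
and shifting (3 voxels) the tumor map → tumor segmentation; dropping one
modality from the manifest → no PNGs. Cohort generation assigns at most
one mode per study (mirroring the accounting rule that a downstream
failure is only noted when upstream processing succeeded); reference
volumes are truth + Gaussian error (default sd 5 cm³, a plausible
inter-method volumetry disagreement).

What the phantoms do *not* model: real anatomy, Rician noise, partial
volume, scanner-specific artifacts, or segmentation-algorithm behavior.
Passing tests therefore demonstrate that rendering, accounting, flag
logic, and aggregation are correct — not that human reviewers or any
segmentation model perform at any particular level on clinical data.

## Numerical and design notes

* Voxel-unit failure magnitudes scale physically with voxel size: at the
  default 3 mm spacing the dilated-and-shifted segmentation stays inside
  the synthetic brain (so it perturbs only the volume QC quantity), while
  on much coarser test grids it can also exit the brain. One-hot
  detectability is therefore a property of the default study conditions.
* Problem sizes used by the test suite and the acceptance script: 20
  seeded studies per failure mode for flag detectability, and a 60-study
  cohort with three modes at rate 0.2 for end-to-end rate recovery and
  RMSE ordering; smaller grids (24³–32³ at the same 192 mm FOV) back the
  purely geometric tests.
* The static gallery is deliberately serverless: client-side search/sort
  only, review via CSV, panels copied into the site so `index.html` works
  from the filesystem with no network. The interactive, reactive-server
  variant of this workflow is out of scope.
* CSF-location semantics are project-specific and stored as an opaque
  string. Functional/derived maps are accepted by name in the manifest
  (`path_func_<name>`) without interpretation.
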