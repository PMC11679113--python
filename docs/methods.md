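# Methods

## Problem and approach

Automated 3-D segmentation models (e.g. multi-organ CT segmenters such as
TotalSegmentator) are routinely used without a practical way to check
their output, because ground-truth masks require expert annotation.
`augseg` estimates mask quality without ground truth by measuring a
model's *self-consistency under invertible spatial augmentation*:

1. sample n invertible augmentations of a scan;
2. segment the original scan and every augmented scan;
3. map each augmented-scan mask back to the original frame with the
   inverse augmentation (producing "inverted segmentation masks", ISMs);
4. score the agreement between the original-scan mask and the ISMs
   (DICE, ASSD, presence/absence errors) and pool the ISMs into a
   voxelwise uncertainty heatmap.

The working hypothesis — validated here synthetically — is that a model
that is inaccurate on a scan is also inconsistent on perturbed versions
of it, so consistency is a usable proxy for accuracy.

## Augmentation model

Three levels, sampled with equal probability:

* **Level 1 — rigid rotation.** Per-axis angles uniform on [−45°, 45°]
  (extrinsic x–y–z composition), about the grid's world-space center.
  The rotation center is our choice (the model is silent in general use):
  it keeps anatomy in frame and matches common augmentation practice.
  Inversion is analytic (transposed matrix).
* **Level 2 — elastic deformation.** A control-point grid (default
  50×50×70) of independent uniform displacements, bounded per axis by a
  quarter of the voxel spacing in mm. The canonical dense field is the
  cubic-spline interpolation of the control grid onto the voxel grid;
  off-grid queries are trilinear in that dense field. Note the bound
  makes the deformation *sub-voxel*: label maps resampled with nearest
  neighbor may be unchanged, while intensity volumes (linear
  interpolation) always change. Inversion solves x + d(x) = y by
  fixed-point iteration (x ← y − d(x)), tolerance 0.1 voxel, max 20
  iterations; convergence is rapid because ‖d‖ ≪ 1 voxel. A failure
  raises with the residual attached.
* **Level 3 — elastic followed by rotation**; the inverse is the
  reversed chain of stage inverses.

Transforms are defined by their *sampling map* (output world coordinate →
input world coordinate), so forward application is always one
interpolation pass: linear with a −1024 HU (air) fill for intensities,
nearest-neighbor with background fill for labels. The output grid equals
the input grid; content rotated out of frame is lost (as in real
acquisition when anatomy leaves the field of view). All sampling is a
pure function of (level, seed, spacing, shape); per-(scan, augmentation)
seeds derive from the master seed by crc32 of `"master:scan_id:index"`.

Interpreting the elastic parameters: "(50, 50, 70)" is read as the
control-grid dimensions along the three axes, and "a quarter of the voxel
spacing" per axis in mm; both are configurable because a 50-point grid on
a small test volume approaches per-voxel displacement — tests and the
synthetic study use a (5, 5, 7) grid.

## Uncertainty

For a voxel with labels L₁…Lₙ from the n ISMs, the agreement fraction is
count(mode)/n and uncertainty = 1 − count(mode)/n, so values live on the
{k/n} lattice: 0 (unanimity, including unanimous background) up to
1 − 1/n (all labels distinct; 0.9 for n = 10). Background is an ordinary
label both voxelwise and in the filewise mean (taken over *all* voxels).
Mode ties do not affect the value; when a mode label is needed it breaks
toward the smaller id. ROI-wise uncertainty averages the map over each
ROI's voxels, with ROI membership defined by the model's own
original-scan mask — ground truth may be absent by design (a ground-truth
reference can be substituted when available); absent ROIs are reported
as missing, never zero.

## Metrics

* **DICE** per class c: 2|A∩B| / (|A|+|B|). A class absent from *both*
  masks is excluded from the average rather than scored 1: over a
  100+-class catalog most scans contain few classes, and scoring
  both-empty as 1 would inflate averages. A class present in exactly one
  mask scores 0. Presence/absence disagreements are tallied separately as
  Type 1 (present in the first mask, missing in the second) and Type 2
  (the reverse) errors; the error rate is total errors over
  (catalog size × number of files), in percent.
* **ASSD** in mm: surfaces are foreground voxels with ≥ 1 face-adjacent
  (6-connectivity) background neighbor, grid edges counting as
  background; distances are Euclidean in world mm via the distance
  transform; the symmetric sum is divided by the total surface count.
  Undefined (missing) when either mask is empty.
* **CV**: sample (n−1) standard deviation over mean; categories low
  (< 0.1), medium ([0.1, 0.3)), high (≥ 0.3). Zero mean → missing;
  single score → 0.
* **Augmentation loss**: 1 − AverageDice(ground truth, ground truth
  pushed through forward-then-inverse augmentation); isolates the
  resampling degradation from model error.
* **Pearson correlations** with two-tailed t-test p-values
  (t = r√((n−2)/(1−r²)), n−2 df). Pairwise-complete deletion for missing
  cells; constant or < 3-pair columns are undefined and reported missing.
  P-values are raw — no multiple-testing correction is applied, so with
  many metric pairs some small p-values are expected by chance.

## Synthetic phantoms and the proxy-validation study

Phantoms are disjoint ellipsoidal ROIs with distinct per-ROI intensities
over an air background plus Gaussian noise, on a 64×64×96 grid at
anisotropic (1.6, 1.6, 1.0) mm spacing — a compact ~10×10×10 cm field of
view so that ±45° rotations keep the "anatomy" in frame, mirroring real
scans where the body sits near the scanner isocenter. ROI centers are
confined to the central 70% of the grid for the same reason: a structure
at the field edge is destroyed by any augmentation regardless of model
quality, which measures acquisition truncation rather than model
inconsistency. Ellipsoids (rather than anatomical atlases) keep volumes
and surfaces in closed form for test oracles, and their size/position
are directly controllable.

Model error is emulated by a *corrupted oracle*: a segmenter that
ignores intensities and returns the known truth degraded by (i) boundary
flips — each surface voxel relabeled to background with probability p,
(ii) whole-ROI dropout, and (iii) optional morphological dilation/erosion
bias. Each call is deterministic in (seed, truth content, affine, salt);
the pipeline salts each augmentation index so every augmented scan is
corrupted independently — the way a real model errs independently per
input — even when a sub-voxel augmentation leaves the resampled truth
identical to the original.

The validation study runs 20 phantoms × 6 severities (boundary-flip rate
0–0.5, dropout rate severity/5) × 5 augmentations. Corruption streams
and transforms are held fixed across severities, so sweeps are nested
and monotone by construction. For each phantom × severity it computes
true quality (DICE of the oracle's original-scan mask against the
constructive truth) and the consistency proxy (mean DICE of the
original-scan mask against the 5 ISMs), plus filewise uncertainty. The
suite requires Pearson r(true, proxy) ≥ 0.7 and mean uncertainty
nondecreasing in severity; observed values are r ≈ 0.87–0.93 across
seeds. Because the oracle corrupts masks directly, the study does not
materialize augmented intensity volumes (the full pipeline does, for
intensity-based segmenters).

What this does and does not show: the phantoms have none of real CT's
texture, artifacts, pathology, or anatomy-dependent failure modes, and
the corrupted oracle's errors are unstructured by design. Passing the
study shows the *machinery* is sound — that when a segmenter's accuracy
degrades, the consistency proxy and uncertainty respond — not that any
particular clinical model's inconsistency equals its inaccuracy.

## Numerical choices and degenerate inputs

* Label maps are stored as the smallest unsigned integer type that holds
  the max label (8-bit up to 255, else 16-bit); non-integer voxel values
  beyond 1e-6 are a format error.
* Spacing is always derived from affine column norms; no canonical
  reorientation is forced (transforms act in world space).
* Fixed-point inversion tolerance 0.1 voxel; the package-wide round-trip
  guarantee (tested over all levels) is 0.25 voxel, and mask
  forward+inverse round trips keep DICE ≥ 0.95 on smooth phantoms —
  quantifying nearest-neighbor resampling loss.
* Empty masks: DICE missing (both empty) or 0 (one empty); ASSD missing;
  uncertainty well-defined (background is a label).
* Failures never silently shrink denominators: per-item failures are
  logged and `n_effective` is explicit in every aggregate.

## Known limitations

* Elastic inversion is numerical; exactness is guaranteed only for
  rotations.
* The ISM comparison inherits resampling loss (~1–3% DICE on smooth
  shapes), so proxy DICE is biased slightly below true DICE even for a
  perfect model; the augmentation-loss metric quantifies this bias.
* The error-rate denominator uses the full catalog size, matching the
  reference tooling's fixed catalog; catalogs with classes that can
  never appear deflate the rate.
* Correlation p-values are raw (see above).
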