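# Methods

`mrseg` implements a semi-automatic tumor-segmentation pipeline for
multi-sequence rectal MRI: voxelwise two-class classification of
anatomical and functional image intensities, followed by a
watershed-based semi-automatic post-processing step, evaluated by Dice
overlap and mean symmetric surface distance (MSD) under patient-level
leave-one-out cross-validation (LOO-CV).  Because clinical multi-sequence
rectal MRI with double expert delineations is not publicly available,
the package ships a synthetic phantom generator so the full pipeline can
be simulated, tested and benchmarked end to end.

## The segmentation model

Each voxel of a patient's region of interest (ROI) is described by raw
intensities:

| block  | features | content                                                          |
|--------|----------|------------------------------------------------------------------|
| T2w    | 9        | the voxel and its eight in-plane neighbors, sorted ascending      |
| T2\*w  | 5        | the five echo images (TE = 4.6–41.4 ms), ascending TE             |
| DW     | 7        | the seven b-value images (b = 0–1300 s/mm²), ascending b          |
| DME    | 42       | 14 selected dynamic time points × 3 echoes, time-major then echo  |

Blocks concatenate in the fixed order (T2w, T2\*w, DW, DME) restricted
to the chosen feature set (15 non-empty combinations).  Features are
z-scored per feature column *within each patient* over the ROI voxels,
which removes inter-patient intensity scale differences and guarantees
that no statistics flow between training and test patients.  Class
imbalance is removed per patient by randomly undersampling non-tumor
voxels to the tumor count (all tumor voxels are kept).

Four classifier families are supported through scikit-learn: linear and
quadratic discriminant analysis (LDA/QDA, no shrinkage; LDA uses the
least-squares solver), a linear support vector machine (C = 1) and
adaptive boosting of depth-1 decision trees (100 rounds, learning rate
1).  These hyperparameters are deliberate defaults — the approach
assumes library-default behaviour rather than tuned models — and every
one is overridable through `ClassifierKind(name, hyperparams)`.

`SegmentationModel(cohort, classifier, feature_set).fit(seed)` runs the
LOO-CV: for each patient a classifier trained on the pooled balanced
matrices of all other patients predicts every ROI voxel of the held-out
patient with the classifier's native decision rule (0.5 posterior / sign
of margin; no threshold tuning).  The returned `SegmentationResults`
carries per-patient Dice/MSD records, the masks, and a `summary()`
table.  Per-patient sub-seeds are derived from the master seed and a
CRC-32 of the patient id, so results are independent of cohort ordering.

## Preprocessing

**Dynamic time-point selection.**  The dynamic multi-echo (DME) contrast
series is acquired for 60+ frames; 14 are selected to normalise temporal
sampling across patients: starting at contrast arrival, the eight frames
closest to a 4 s temporal resolution, then six frames at 80 s resolution
(nominal offsets 0, 4, …, 28, 108, 188, …, 508 s after arrival).  Ties
break toward the earlier frame; a frame already taken is replaced by the
next unused nearest frame.  Contrast-arrival time is taken from metadata
(the phantom generator records it); automatic bolus-arrival detection is
out of scope.

**ROI and resampling.**  A cuboid box with a 20 mm margin (default)
around the union of the two observer delineations, clipped to the field
of view common to all sequences, defines the analysis region.  All
sequences are rigidly registered (6 DOF, Mattes mutual information,
two-level multi-resolution, T2w fixed, metric restricted to the box) and
resampled onto a 1 mm isotropic grid covering the box — linear
interpolation for images, nearest-neighbor for masks.  One transform is
estimated per sequence from its most contrast-bearing channel (longest
echo, highest b-value, first dynamic frame's longest echo) and applied
to all channels of that sequence.  Mutual information is the standard
cross-contrast metric choice; no claim is made that it matches any
particular prior implementation.

## Post-processing

The raw voxelwise prediction is (1) smoothed with a 3×3×3 median filter,
(2) split into regions by a watershed on the negated Euclidean distance
transform — markers are the regional maxima of the distance map after
h-maxima suppression with h = 1 mm, with a fallback marker at the
deepest voxel of any component left markerless, 26-connectivity
throughout — and (3) reduced to the regions hit by simulated user seeds:
one voxel per axial slice sampled uniformly inside the ground-truth
delineation.  A seed landing on a watershed line snaps to the nearest
labeled voxel within 1 mm, otherwise it is ignored.  The final mask is
always a subset of the smoothed prediction.  Median kernel, h, and the
snap radius are configurable; filtering and watershed act in 3D (a 2D
per-slice variant was a plausible alternative and is documented as such,
not implemented).

## Evaluation

Dice = 2|P∩G| / (|P|+|G|).  MSD sums, over the surface voxels of the
ground truth G and prediction P, the minimal 3D Euclidean distance (mm)
to the other surface, normalised by the total surface voxel count
(N_G + N_P).  Surfaces are mask voxels with a face-adjacent
(6-connectivity) background neighbor, the volume border counting as
background, and distances are measured between voxel centers in physical
coordinates — a sub-voxel mesh surface would be a different, equally
defensible convention, so exact equality with other MSD implementations
is not claimed.  An empty prediction is flagged (Dice 0, MSD undefined)
rather than scored.  Cohort values are summarized as median (MED) and
interquartile range (IQR, Q3−Q1 with linear-interpolation quantiles).

## Experiments and statistics

Two cohort experiments mirror the study design.  The *algorithm
comparison* runs LDA/QDA/SVM/ADA on T2w features; a Friedman test for
repeated measurements gates all C(4,2) = 6 pairwise two-sided Wilcoxon
signed-rank tests, Bonferroni-corrected by 6.  The *feature-set
comparison* runs one classifier (ADA by default) over feature-set
combinations and compares each against the T2w-only reference by
Wilcoxon, Bonferroni-corrected by the number of comparisons (14 when all
15 combinations run).  The Bonferroni family sizes are inferred from the
comparisons actually made; exact Wilcoxon p-values are used for n ≤ 25
when ties permit, the normal approximation otherwise, and identical
paired samples yield p = 1.  A run manifest (full config, master seed,
per-patient fold seeds, library versions) makes every run reproducible
bit-for-bit via `rerun_from_manifest`.

## The phantom generator

The generator emulates one patient study: a tumor — an ellipsoid with a
smooth random radial boundary perturbation (relative amplitude 0.08) —
embedded in homogeneous normal tissue, rendered per sequence on that
sequence's own acquisition grid.  Default grids follow a clinical
protocol (T2w 256×254 at 0.35 mm in plane, 2.75 mm slices; T2\*w 180×120
at 0.70 mm; DW 80×60 at 1.25 mm; DME 92×90 at 0.70 mm, 10 mm slices at
5 mm separation), with slice counts covering ~60 mm of anatomy.

Signal models per tissue:

* DW: S(b) = S0·exp(−b·ADC), defaults ADC 1.0×10⁻³ (tumor) vs
  1.6×10⁻³ mm²/s (normal);
* T2\*w: S(TE) = S0·exp(−TE/T2\*), defaults T2\* 35 vs 55 ms;
* T2w: constant tissue means (550 vs 400, arbitrary units);
* DME: the T2\* echo decay modulated, from contrast arrival t_arr, by
  the uptake–washout factor
  1 + A·(1 − e^(−k_in(t−t_arr)))·e^(−k_out(t−t_arr)) (defaults tumor
  A = 1.2, k_in = 0.05 s⁻¹, k_out = 0.002 s⁻¹; normal A = 0.5, 0.02,
  0.001), baseline before arrival.  This parametric curve emulates a
  contrast-uptake time course without committing to a pharmacokinetic
  model.  The default acquisition is a split dynamic series (4 s frames
  through the first minute, 20 s frames to 620 s) with arrival at 12 s.

Each sequence carries its own small rigid misalignment (≤ ~1.5 mm
translations by default) and additive Gaussian noise.  Gaussian rather
than Rician noise is a deliberate simplification: downstream methods are
noise-model-agnostic, and at the phantom's signal-to-noise levels the
difference is immaterial for classification.  The truth mask is the
voxelization (voxel-center rule) of the analytic shape on the T2w grid.

Tissue contrast levels are free parameters of the phantom, not claims
about real tissue — no published intensity statistics exist for tumor
versus normal rectal wall in these units.

**Simulated observers.**  Two delineations are derived from the truth by
warping its signed distance function with independent smooth random
displacement fields (Gaussian-smoothed white noise, 6 mm correlation
scale).  The field is scaled so its *maximum* magnitude equals the
amplitude parameter, which (by the 1-Lipschitz property of the signed
distance) confines each observer between the truth eroded and dilated by
the amplitude.  The default amplitude, 10 mm, was calibrated by a
Monte-Carlo sweep on a 30 mm sphere at 1 mm resolution (24 seeds per
amplitude) to give a median observer-pair Dice of 0.83, matching
reported expert interobserver agreement for rectal tumors (~0.82).  The
union of the two observers is the training/evaluation ground truth.

**What the phantom does not model:** partial-volume averaging beyond
grid resampling, k-space acquisition effects, bias fields, motion,
Rician noise floors, anatomical background structure, or deformable
(non-rigid) inter-sequence motion.  Passing simulation tests therefore
demonstrates the correctness and internal consistency of the pipeline,
not clinical-grade accuracy on patient images.

## Simulation study conditions

Cohort experiments run on desk-scale phantoms (`PhantomSpec.small` and
the presets in `mrseg.presets`); the problem sizes below are the
package's chosen simulation conditions.

* *Easy recovery* (8 patients): 1.25 mm isotropic grids, ~16 mm tumors,
  strong contrast in every sequence, low noise, aligned sequences,
  1.5 mm observer amplitude, 12 mm ROI margin.  Under these conditions
  LOO-CV ADA recovers the union ground truth with median post-processed
  Dice above 0.9 for every single-sequence feature set.
* *DME-only contrast* (20 patients): tumor and normal tissue identical
  except the DCE uptake amplitude (1.4 vs 0.5), so only feature sets
  containing DME carry signal; T2w+DME then outperforms T2w alone —
  the qualitative direction expected when dynamic contrast is the
  informative sequence.
* *Null control* (12 patients, 50 repetitions, LDA): no tissue contrast
  anywhere; the fraction of feature-set comparisons declared significant
  after Bonferroni estimates the type-I error of the comparison
  machinery.  Twelve patients is the smallest cohort at which a
  Bonferroni-corrected exact Wilcoxon test (×14) can reach 0.05 at all.

These presets use a minimal dynamic acquisition whose frames sit exactly
on the nominal 14-frame schedule; the full split acquisition is covered
by the phantom defaults and the selection tests.

## Numerical choices and degenerate inputs

* Tie-breaks: dynamic-frame selection prefers the earlier frame; sorted
  T2w neighborhoods break ties by value order (stable sort).
* T2w 3×3 patches at the volume edge replicate the edge voxel; the ROI
  margin makes edge voxels rare in practice.
* Zero-variance feature columns (possible in noiseless degenerate
  phantoms, e.g. the b = 0 channel) raise an explicit error rather than
  dividing by zero.
* A patient with fewer non-tumor than tumor ROI voxels keeps all
  non-tumor rows under balancing, with a warning.
* Empty predicted masks are flagged; Dice is reported as 0 and MSD as
  undefined.
* Watershed on an empty mask returns an empty label map (no error);
  every connected component is guaranteed a marker so labeled voxels
  always tile the smoothed mask.
* All randomness flows from explicit seeds; per-patient sub-seeds hash
  the patient id so cohort order is irrelevant.

## Known limitations

* The phantom's two-tissue world makes voxelwise classification easier
  than on real anatomy; absolute Dice values from simulations are not
  comparable to patient-cohort values.
* Interpolated resampling of a two-valued phantom creates a boundary
  band of intermediate intensities; with coarse acquisition grids this
  band, not classifier quality, limits attainable Dice.
* Rigid registration only; deformable motion between sequences is not
  corrected (or simulated).
* The z-score scope is per feature column within patient; pooling all
  channels of a sequence into one distribution is a defensible
  alternative reading and would change scale relationships between
  channels.
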