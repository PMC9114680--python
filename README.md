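# mrseg

Semi-automatic tumor segmentation for multi-sequence rectal MRI:
voxelwise machine-learning classification of anatomical and functional
image intensities, followed by a watershed-based semi-automatic
post-processing step, evaluated with the Sørensen–Dice coefficient and
the mean symmetric surface distance under patient-level leave-one-out
cross-validation.

The package is aimed at medical-image-analysis researchers who want to
study how combining anatomical T2-weighted (T2w) MRI with functional
sequences — multi-echo T2\*-weighted (T2\*w), diffusion-weighted (DW)
and dynamic multi-echo contrast-enhanced (DME) MRI — affects
segmentation quality.  Because multi-sequence patient data with double
expert delineations is rarely shareable, `mrseg` includes a synthetic
phantom generator that emulates the full acquisition (per-sequence
grids, mono-exponential diffusion and T2\* decay, a contrast-uptake time
course, rigid inter-sequence misalignment, noise, and two simulated
observer delineations), so every stage is testable and complete
simulation studies run on a laptop.

## The method

Segmentation is treated as two-class voxel classification inside a
region of interest (a box with a 20 mm margin around the union of two
observer delineations, resampled to 1 mm³ after rigid registration of
all sequences to the T2w reference).  Per voxel the features are raw
intensities: the sorted 3×3 in-plane T2w neighborhood (9), the five
T2\*w echoes, the seven DW b-value images, and 14 selected dynamic time
points × 3 echoes (42).  Features are z-scored per patient, classes
balanced per patient by random undersampling, and one of LDA, QDA,
linear SVM or AdaBoost (decision stumps) is trained on the pooled
training patients.  The predicted mask is median-filtered, split into
regions by a watershed on the Euclidean distance transform, and reduced
to the regions containing simulated user seeds (one per axial slice
inside the ground truth).  Quality is measured by

* DICE = 2|P∩G| / (|P|+|G|), and
* MSD = (Σ d(i, G→P) + Σ d(i, P→G)) / (N_G + N_P), the symmetric mean
  of minimal surface-voxel distances in mm,

summarized as median (MED) and interquartile range (IQR) over patients,
with Friedman and Bonferroni-corrected Wilcoxon signed-rank tests for
algorithm and feature-set comparisons.  See `docs/methods.md` for the
full model description.

## Worked example

```python
from mrseg import SegmentationModel
from mrseg.experiment import build_cohort
from mrseg.presets import easy_recovery_config

config = easy_recovery_config(n_patients=4, master_seed=7)
cohort = build_cohort(config)          # four synthetic patients

model = SegmentationModel(
    cohort,
    classifier="ADA",
    feature_set=("T2w", "DME"),
    margin_mm=12.0,
    register=False,                    # phantom sequences are aligned
)
results = model.fit(seed=7)
print(results.summary())
```

which prints

```
Voxelwise segmentation (leave-one-out CV)
  classifier : ADA {'n_estimators': 100, 'learning_rate': 1.0, 'max_depth': 1}
  features   : T2w+DME
  patients   : 4
  DICE MED [IQR] : 0.931 [0.014]
  MSD  MED [IQR] : 0.34 [0.08] mm
```

Each of the four phantoms was segmented by an AdaBoost model trained on
the other three; the median post-processed overlap with the union
ground truth is Dice 0.931 and the surfaces lie 0.34 mm apart on
average — near-perfect recovery, as expected on this favourable
high-contrast cohort.  `results.to_frame()` gives the per-patient
records, and `run_algorithm_comparison` / `run_featureset_comparison`
in `mrseg.experiment` run the full cohort studies with statistics and
CSV/manifest reports.

A command-line front end covers the common steps:

```bash
mrseg phantom --base small --seed 3 --out study/       # NIfTI + JSON sidecar
mrseg preprocess --in study/ --out prep/ --margin 20
mrseg evaluate --pred pred.nii.gz --gt truth.nii.gz
mrseg experiment --config cfg.yaml --out report/       # cfg.yaml: ExperimentConfig fields
```

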