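"""Canned study conditions for simulation experiments.

Each preset returns an :class:`~mrseg.experiment.ExperimentConfig` whose
phantom cohort realises one experimental regime:

* :func:`easy_recovery_config` — a favourable cohort (large tumor
  relative to voxel size, strong contrast in every sequence, low noise,
  aligned sequences, small observer variation) on which a voxelwise
  classifier should recover the tumor almost perfectly; used to verify
  end-to-end pipeline integrity.
* :func:`dme_contrast_config` — tumor and normal tissue are identical in
  every sequence except the dynamic contrast-uptake amplitude, so only
  feature sets containing DME carry tumor signal; used to demonstrate
  the benefit of adding dynamic contrast features to T2w.
* :func:`null_contrast_config` — tumor and normal tissue are identical
  everywhere; any "significant" feature-set difference is a false
  positive, so repeated runs estimate the type-I error of the comparison
  machinery.

All presets use a minimal dynamic acquisition whose frames sit exactly
on the nominal 14-frame selection schedule (arrival at t = 0), keeping
cohort simulation fast; the full split dynamic acquisition is exercised
by the phantom defaults and the preprocessing tests.
"""

from __future__ import annotations

from . import phantom as ph
from .experiment import ExperimentConfig
from .phantom import DME, DW, T2SW, T2W, GridSpec, RigidParams, TissueParams

#: The 14 nominal dynamic frame times (s) with contrast arrival at t = 0.
NOMINAL_ACQUISITION_S = (
    0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0,
    108.0, 188.0, 268.0, 348.0, 428.0, 508.0,
)

_ALIGNED = {k: RigidParams() for k in (T2W, T2SW, DW, DME)}


def easy_recovery_config(n_patients: int = 8, master_seed: int = 0) -> ExperimentConfig:
    """Favourable cohort for end-to-end recovery checks.

    1.25 mm isotropic grids for every sequence, a ~16 mm tumor, strong
    tumor/normal contrast in all four sequences, low noise, no
    inter-sequence misalignment and a small observer perturbation.
    """
    grid = GridSpec((38, 38, 32), (1.25, 1.25, 1.25))
    return ExperimentConfig(
        n_patients=n_patients,
        master_seed=master_seed,
        phantom_base="small",
        phantom_overrides=dict(
            grids={T2W: grid, T2SW: grid, DW: grid, DME: grid},
            tumor_semiaxes_mm=(8.0, 7.0, 6.0),
            tumor=TissueParams(
                adc=0.8e-3, t2star_ms=25.0, t2w_mean=600.0,
                dce_amplitude=1.5, dce_kin=0.06, dce_kout=0.002,
            ),
            normal=TissueParams(
                adc=1.8e-3, t2star_ms=60.0, t2w_mean=400.0,
                dce_amplitude=0.3, dce_kin=0.02, dce_kout=0.001,
            ),
            noise_sigma={T2W: 5.0, T2SW: 10.0, DW: 10.0, DME: 8.0},
            observer_amplitude_mm=1.5,
            misalignment=_ALIGNED,
            timestamps_s=NOMINAL_ACQUISITION_S,
            arrival_s=0.0,
        ),
        center_jitter_mm=1.5,
        semiaxis_jitter_frac=0.10,
        margin_mm=12.0,
        register=False,
        best_classifier="ADA",
        # 40 boosting rounds: ample for the strong-contrast regime and
        # keeps the 8-patient x 4-feature-set simulation fast
        hyperparams={"ADA": {"n_estimators": 40}},
    )


def _flat_tissue() -> TissueParams:
    return TissueParams(
        adc=1.3e-3, t2star_ms=45.0, t2w_mean=450.0,
        dce_amplitude=0.5, dce_kin=0.03, dce_kout=0.001,
    )


def dme_contrast_config(n_patients: int = 20, master_seed: int = 0) -> ExperimentConfig:
    """Cohort whose only tumor/normal separation is the DCE uptake amplitude."""
    grid = GridSpec((18, 18, 14), (2.5, 2.5, 2.5))
    tumor = _flat_tissue()
    tumor = TissueParams(**{**tumor.__dict__, "dce_amplitude": 1.4})
    return ExperimentConfig(
        n_patients=n_patients,
        master_seed=master_seed,
        phantom_base="small",
        phantom_overrides=dict(
            grids={T2W: grid, T2SW: grid, DW: grid, DME: grid},
            tumor_semiaxes_mm=(5.0, 4.5, 4.0),
            tumor=tumor,
            normal=_flat_tissue(),
            noise_sigma={T2W: 8.0, T2SW: 8.0, DW: 8.0, DME: 8.0},
            observer_amplitude_mm=1.5,
            misalignment=_ALIGNED,
            timestamps_s=NOMINAL_ACQUISITION_S,
            arrival_s=0.0,
        ),
        center_jitter_mm=1.5,
        semiaxis_jitter_frac=0.10,
        margin_mm=8.0,
        register=False,
        best_classifier="ADA",
        hyperparams={"ADA": {"n_estimators": 40}},
        descriptors=((T2W,), (T2W, DME)),
    )


def null_contrast_config(n_patients: int = 12, master_seed: int = 0) -> ExperimentConfig:
    """Contrast-free cohort: tumor and normal tissue are indistinguishable."""
    grid = GridSpec((14, 14, 11), (2.5, 2.5, 2.5))
    return ExperimentConfig(
        n_patients=n_patients,
        master_seed=master_seed,
        phantom_base="small",
        phantom_overrides=dict(
            grids={T2W: grid, T2SW: grid, DW: grid, DME: grid},
            tumor_semiaxes_mm=(5.0, 4.5, 4.0),
            tumor=_flat_tissue(),
            normal=_flat_tissue(),
            noise_sigma={T2W: 8.0, T2SW: 8.0, DW: 8.0, DME: 8.0},
            observer_amplitude_mm=1.5,
            misalignment=_ALIGNED,
            timestamps_s=NOMINAL_ACQUISITION_S,
            arrival_s=0.0,
        ),
        center_jitter_mm=1.5,
        semiaxis_jitter_frac=0.10,
        margin_mm=5.0,
        register=False,
        best_classifier="LDA",
    )
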