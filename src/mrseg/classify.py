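"""Voxelwise binary classification and patient-level leave-one-out CV.

Four classifier families are supported — linear discriminant analysis
(LDA), quadratic discriminant analysis (QDA), a linear support vector
machine (SVM) and adaptive boosting of decision stumps (ADA) — all via
scikit-learn, with hyperparameters recorded for reproducibility.

``SegmentationModel`` ties the pipeline together in the style of a
statistical modelling package: it is constructed from a cohort of
studies plus the classifier kind and feature set, and ``fit(seed)``
runs patient-level leave-one-out cross-validation (per-patient z-scored
features, per-patient class balancing, pooled training, full-ROI
prediction, semi-automatic post-processing, Dice/MSD evaluation) and
returns a ``SegmentationResults`` object carrying the per-patient
records, the cohort summaries and the predicted masks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import features as ft
from . import metrics as mx
from . import postprocess as pp
from . import preprocess as pre
from . import phantom as ph
from .volume import ImageVolume

CLASSIFIER_KINDS = ("LDA", "QDA", "SVM", "ADA")

#: Hyperparameters used when the caller does not override them.  The SVM
#: uses a linear kernel with unit regularization; ADA boosts depth-1
#: trees (stumps) for 100 rounds at learning rate 1; LDA/QDA use no
#: shrinkage/regularization.
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "LDA": {"solver": "lsqr"},
    "QDA": {"reg_param": 0.0},
    "SVM": {"kernel": "linear", "C": 1.0},
    "ADA": {"n_estimators": 100, "learning_rate": 1.0, "max_depth": 1},
}


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierKind:
    """A classifier family plus its fully-specified hyperparameters."""

    name: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in CLASSIFIER_KINDS:
            raise TrainingError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_KINDS}"
            )
        merged = {**DEFAULT_HYPERPARAMS[self.name], **self.hyperparams}
        object.__setattr__(self, "hyperparams", merged)

    def build(self, seed: int):
        hp = self.hyperparams
        if self.name == "LDA":
            return LinearDiscriminantAnalysis(**hp)
        if self.name == "QDA":
            return QuadraticDiscriminantAnalysis(**hp)
        if self.name == "SVM":
            return SVC(random_state=seed, **hp)
        base = DecisionTreeClassifier(max_depth=hp["max_depth"], random_state=seed)
        return AdaBoostClassifier(
            estimator=base,
            n_estimators=hp["n_estimators"],
            learning_rate=hp["learning_rate"],
            random_state=seed,
        )


def _as_kind(kind) -> ClassifierKind:
    return kind if isinstance(kind, ClassifierKind) else ClassifierKind(str(kind))


@dataclass
class TrainedModel:
    """A fitted voxel classifier plus its provenance."""

    kind: ClassifierKind
    descriptor: ft.FeatureSetDescriptor
    estimator: object
    training_patients: tuple[str, ...]
    seed: int

    def predict(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(values)).astype(np.int8)


def _stable_patient_seed(master_seed: int, patient_id: str, salt: int = 0) -> int:
    """A per-patient seed independent of cohort ordering."""
    h = zlib.crc32(patient_id.encode())
    ss = np.random.SeedSequence([int(master_seed), h, salt])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def train(
    kind,
    matrices: "list[ft.FeatureMatrix]",
    seed: int = 0,
) -> TrainedModel:
    """Fit a classifier on pooled, class-balanced patient matrices.

    All matrices must share a feature-set descriptor; patients are pooled
    in patient-id order so the fit does not depend on list ordering.
    """
    kind = _as_kind(kind)
    if not matrices:
        raise TrainingError("no training matrices")
    desc = matrices[0].descriptor
    for m in matrices[1:]:
        if m.descriptor != desc:
            raise TrainingError(
                f"descriptor mismatch: {m.descriptor} vs {desc}"
            )
    ordered = sorted(matrices, key=lambda m: m.patient_id)
    X = np.concatenate([m.values for m in ordered], axis=0)
    y = np.concatenate([m.labels for m in ordered], axis=0)
    if np.unique(y).size < 2:
        raise TrainingError("training data contains a single class")
    est = kind.build(seed)
    est.fit(X, y)
    return TrainedModel(
        kind=kind,
        descriptor=desc,
        estimator=est,
        training_patients=tuple(m.patient_id for m in ordered),
        seed=int(seed),
    )


def predict_volume(
    model: TrainedModel,
    study: ph.MultiSequenceStudy,
    matrix: ft.FeatureMatrix | None = None,
) -> ImageVolume:
    """Predict a binary tumor mask over the full ROI of one patient.

    The study must be preprocessed; features are z-scored with the test
    patient's own statistics (no information flows from the training
    cohort).  Every ROI voxel is scored with the classifier's native
    decision rule.
    """
    if matrix is None:
        matrix = ft.patient_matrix(study, model.descriptor)
    if matrix.descriptor != model.descriptor:
        raise TrainingError(
            f"descriptor mismatch: model {model.descriptor}, matrix {matrix.descriptor}"
        )
    pred = model.predict(matrix.values)
    shape = study.t2w.data.shape
    mask = np.zeros(shape, dtype=bool)
    idx = matrix.voxel_indices
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = pred.astype(bool)
    return study.t2w.with_data(mask, mask="prediction")


def loo_cv(
    cohort: "list[ph.MultiSequenceStudy]",
    kind,
    descriptor: ft.FeatureSetDescriptor,
    seed: int = 0,
    matrices: dict | None = None,
) -> "list[pp.SegmentationResult]":
    """Patient-level leave-one-out cross-validation.

    For every patient, a classifier is trained on the pooled balanced
    matrices of all *other* patients and predicts the held-out patient's
    full ROI.  Per-patient seeds are derived deterministically from the
    master seed and the patient id, so fold results do not depend on the
    cohort ordering.  ``matrices`` may carry precomputed full-ROI
    normalized matrices keyed by patient id (an optimisation when many
    classifiers share a feature set).
    """
    kind = _as_kind(kind)
    if len(cohort) < 2:
        raise TrainingError("leave-one-out needs at least 2 patients")
    ids = [s.patient_id for s in cohort]
    if len(set(ids)) != len(ids):
        raise TrainingError("duplicate patient ids in cohort")
    if matrices is None:
        matrices = {s.patient_id: ft.patient_matrix(s, descriptor) for s in cohort}
    balanced = {
        pid: ft.undersample(matrices[pid], _stable_patient_seed(seed, pid, salt=1))
        for pid in ids
    }
    results = []
    for study in cohort:
        held = study.patient_id
        train_mats = [balanced[pid] for pid in ids if pid != held]
        fold_seed = _stable_patient_seed(seed, held, salt=2)
        model = train(kind, train_mats, seed=fold_seed)
        assert held not in model.training_patients
        raw = predict_volume(model, study, matrix=matrices[held])
        results.append(pp.SegmentationResult(patient_id=held, raw_mask=raw))
    return results


# ---------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------

class SegmentationModel:
    """Cohort-level segmentation model in fit/results style.

    Parameters
    ----------
    cohort : list of MultiSequenceStudy
        Patient studies; preprocessed studies are used as-is, raw studies
        are preprocessed on fit.
    classifier : str or ClassifierKind
        One of LDA, QDA, SVM, ADA.
    feature_set : FeatureSetDescriptor or iterable of str
        Sequences whose features enter the model.
    margin_mm, register :
        Preprocessing parameters (ROI margin and whether rigid transforms
        are estimated rather than assumed identity).
    median_radius, h_mm, snap_mm :
        Post-processing parameters.
    """

    def __init__(
        self,
        cohort,
        classifier="ADA",
        feature_set=(ph.T2W,),
        margin_mm: float = 20.0,
        register: bool = True,
        median_radius: int = 1,
        h_mm: float = 1.0,
        snap_mm: float = 1.0,
    ):
        self.cohort = list(cohort)
        self.kind = _as_kind(classifier)
        self.descriptor = (
            feature_set
            if isinstance(feature_set, ft.FeatureSetDescriptor)
            else ft.FeatureSetDescriptor(tuple(feature_set))
        )
        self.margin_mm = margin_mm
        self.register = register
        self.median_radius = median_radius
        self.h_mm = h_mm
        self.snap_mm = snap_mm

    def _prepared_cohort(self):
        out = []
        for s in self.cohort:
            if not s.is_preprocessed:
                s = pre.preprocess_study(
                    s, margin_mm=self.margin_mm, estimate_transforms=self.register
                )
            out.append(s)
        return out

    def fit(self, seed: int = 0, matrices: dict | None = None) -> "SegmentationResults":
        cohort = self._prepared_cohort()
        folds = loo_cv(cohort, self.kind, self.descriptor, seed=seed, matrices=matrices)
        records = []
        by_id = {s.patient_id: s for s in cohort}
        for res in folds:
            study = by_id[res.patient_id]
            gt = study.union
            post = pp.postprocess(
                res.raw_mask, gt,
                seed=_stable_patient_seed(seed, res.patient_id, salt=3),
                median_radius=self.median_radius,
                h_mm=self.h_mm, snap_mm=self.snap_mm,
                patient_id=res.patient_id,
            )
            res.post_mask = post.post_mask
            res.seeds = post.seeds
            res.intermediates = post.intermediates
            rec = mx.evaluate_masks(
                post.post_mask, gt,
                patient_id=res.patient_id,
                algorithm=self.kind.name,
                features=str(self.descriptor),
            )
            rec.extras["raw_dice"] = mx.evaluate_masks(res.raw_mask, gt).dice
            records.append(rec)
        return SegmentationResults(model=self, seed=seed, folds=folds, records=records)


class SegmentationResults:
    """Per-patient segmentations and metrics from a fitted model."""

    def __init__(self, model, seed, folds, records):
        self.model = model
        self.seed = seed
        self.folds = folds
        self.records = records

    @property
    def dice(self) -> np.ndarray:
        return np.array([r.dice for r in self.records], dtype=float)

    @property
    def msd(self) -> np.ndarray:
        return np.array(
            [np.nan if r.msd is None else r.msd for r in self.records], dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "algorithm": [r.algorithm for r in self.records],
                "features": [r.features for r in self.records],
                "dice": self.dice,
                "msd": self.msd,
                "empty_prediction": [r.empty_prediction for r in self.records],
            }
        )

    def summary(self) -> str:
        from .experiment import summarize

        med_d, iqr_d = summarize(self.dice.tolist())
        msd_vals = self.msd[~np.isnan(self.msd)]
        lines = [
            "Voxelwise segmentation (leave-one-out CV)",
            f"  classifier : {self.model.kind.name} {self.model.kind.hyperparams}",
            f"  features   : {self.model.descriptor}",
            f"  patients   : {len(self.records)}",
            f"  DICE MED [IQR] : {med_d:.3f} [{iqr_d:.3f}]",
        ]
        if msd_vals.size:
            med_m, iqr_m = summarize(msd_vals.tolist())
            lines.append(f"  MSD  MED [IQR] : {med_m:.2f} [{iqr_m:.2f}] mm")
        n_empty = sum(r.empty_prediction for r in self.records)
        if n_empty:
            lines.append(f"  empty predictions: {n_empty}")
        return "\n".join(lines)
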