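"""Voxelwise feature matrices for the two-class tumor/normal problem.

Per sequence the features of a voxel are raw intensities:

* ``T2w``  — the voxel and its eight in-plane (axial) neighbors, sorted
  ascending by intensity (9 features; out-of-volume neighbors are filled
  by edge replication),
* ``T2*w`` — the five echo-time images, ascending TE (5 features),
* ``DW``   — the seven b-value images, ascending b (7 features),
* ``DME``  — the 14 selected dynamic time points with three echoes each,
  time-major then echo (42 features).

Feature blocks concatenate in the fixed order (T2w, T2*w, DW, DME)
restricted to the requested feature set, so a matrix built for one
patient is column-compatible with any other.  Intensities are z-scored
per feature column within each patient over the ROI voxels, and the
class imbalance is removed per patient by randomly undersampling the
non-tumor voxels to the tumor count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from . import phantom as ph
from .volume import ImageVolume

SEQUENCE_ORDER = (ph.T2W, ph.T2SW, ph.DW, ph.DME)
_FEATURE_COUNTS = {ph.T2W: 9, ph.T2SW: 5, ph.DW: 7, ph.DME: 42}


class FeatureError(ValueError):
    pass


class ZeroVarianceError(FeatureError):
    """A feature column has zero spread within the patient ROI."""


@dataclass(frozen=True)
class FeatureSetDescriptor:
    """An ordered non-empty subset of the four sequence feature blocks."""

    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise FeatureError("feature set must be non-empty")
        unknown = set(self.members) - set(SEQUENCE_ORDER)
        if unknown:
            raise FeatureError(f"unknown sequences {sorted(unknown)}")
        canonical = tuple(s for s in SEQUENCE_ORDER if s in self.members)
        object.__setattr__(self, "members", canonical)

    @classmethod
    def of(cls, *members: str) -> "FeatureSetDescriptor":
        return cls(tuple(members))

    @classmethod
    def all_combinations(cls) -> "list[FeatureSetDescriptor]":
        """The 15 non-empty subsets of {T2w, T2*w, DW, DME}."""
        out = []
        for r in range(1, len(SEQUENCE_ORDER) + 1):
            for combo in combinations(SEQUENCE_ORDER, r):
                out.append(cls(combo))
        return out

    @property
    def n_features(self) -> int:
        return sum(_FEATURE_COUNTS[m] for m in self.members)

    def __str__(self) -> str:
        return "+".join(self.members)


@dataclass
class FeatureMatrix:
    """Voxel-by-feature table with its grid bookkeeping.

    ``voxel_indices`` holds (z, y, x) indices on the ROI grid for each
    row; ``labels`` is 1 for tumor (union ground truth) voxels.
    """

    values: np.ndarray  # (n_voxels, n_features) float
    voxel_indices: np.ndarray  # (n_voxels, 3) int, (z, y, x)
    labels: np.ndarray  # (n_voxels,) in {0, 1}
    patient_id: str
    descriptor: FeatureSetDescriptor
    feature_names: tuple[str, ...]
    norm_stats: dict | None = None  # per-column {"mean": ..., "sd": ...}

    def __post_init__(self):
        if self.values.ndim != 2:
            raise FeatureError("values must be 2D")
        if self.values.shape[1] != self.descriptor.n_features:
            raise FeatureError(
                f"{self.values.shape[1]} columns != descriptor "
                f"{self.descriptor} ({self.descriptor.n_features})"
            )
        if self.values.shape[0] != self.labels.shape[0]:
            raise FeatureError("labels/values row mismatch")
        if np.isnan(self.values).any():
            raise FeatureError("feature matrix contains missing values")

    @property
    def n_tumor(self) -> int:
        return int(self.labels.sum())


# ---------------------------------------------------------------------
# per-sequence feature extraction
# ---------------------------------------------------------------------

def _t2w_feature_stack(volume: ImageVolume) -> np.ndarray:
    """Sorted 3x3 in-plane neighborhoods for every voxel, shape (nz,ny,nx,9)."""
    data = np.asarray(volume.data, dtype=float)
    padded = np.pad(data, ((0, 0), (1, 1), (1, 1)), mode="edge")
    shifts = []
    for dy in (0, 1, 2):
        for dx in (0, 1, 2):
            shifts.append(
                padded[:, dy : dy + data.shape[1], dx : dx + data.shape[2]]
            )
    patch = np.stack(shifts, axis=-1)
    patch.sort(axis=-1)
    return patch


def t2w_features(volume: ImageVolume, voxel: tuple[int, int, int]) -> np.ndarray:
    """The nine sorted in-plane neighborhood intensities of one voxel.

    ``voxel`` is a (z, y, x) index; neighbors outside the volume are
    filled by replicating the edge voxel.
    """
    z, y, x = voxel
    nz, ny, nx = volume.data.shape
    if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
        raise FeatureError(f"voxel {voxel} outside volume of shape {(nz, ny, nx)}")
    data = np.asarray(volume.data, dtype=float)
    ys = np.clip(np.arange(y - 1, y + 2), 0, ny - 1)
    xs = np.clip(np.arange(x - 1, x + 2), 0, nx - 1)
    patch = data[z][np.ix_(ys, xs)].ravel()
    return np.sort(patch)


def _channel_stack(study: ph.MultiSequenceStudy, sequence: str) -> list[ImageVolume]:
    """Channels of a sequence in canonical feature order (with names)."""
    if sequence == ph.T2W:
        return [study.t2w]
    if sequence == ph.T2SW:
        return sorted(study.t2sw, key=lambda v: v.channel["te_ms"])
    if sequence == ph.DW:
        return sorted(study.dw, key=lambda v: v.channel["b"])
    if sequence == ph.DME:
        # time-major then echo; preprocessing has reduced dme to the 14
        # selected frames in temporal order
        out = []
        for frame in study.dme:
            out.extend(sorted(frame, key=lambda v: v.channel["te_ms"]))
        return out
    raise FeatureError(f"unknown sequence {sequence!r}")


def _feature_names(sequence: str, channels: list[ImageVolume]) -> list[str]:
    if sequence == ph.T2W:
        return [f"T2w_rank{k}" for k in range(9)]
    if sequence == ph.T2SW:
        return [f"T2*w_te{v.channel['te_ms']:g}" for v in channels]
    if sequence == ph.DW:
        return [f"DW_b{v.channel['b']:g}" for v in channels]
    return [f"DME_t{v.channel['t_s']:g}_te{v.channel['te_ms']:g}" for v in channels]


def sequence_features(
    study: ph.MultiSequenceStudy,
    voxel: tuple[int, int, int],
    descriptor: FeatureSetDescriptor,
) -> np.ndarray:
    """Feature vector of one voxel of a preprocessed study."""
    parts = []
    for seq in descriptor.members:
        chans = _channel_stack(study, seq)
        _check_counts(seq, chans)
        if seq == ph.T2W:
            parts.append(t2w_features(study.t2w, voxel))
        else:
            z, y, x = voxel
            parts.append(np.array([float(c.data[z, y, x]) for c in chans]))
    return np.concatenate(parts)


def _check_counts(sequence: str, channels: list[ImageVolume]) -> None:
    expected = _FEATURE_COUNTS[sequence] if sequence != ph.T2W else 1
    if len(channels) != expected:
        raise FeatureError(
            f"sequence {sequence} has {len(channels)} channels, expected {expected}"
        )


# ---------------------------------------------------------------------
# matrix assembly, normalization, balancing
# ---------------------------------------------------------------------

def assemble_matrix(
    study: ph.MultiSequenceStudy,
    descriptor: FeatureSetDescriptor,
    box=None,
) -> FeatureMatrix:
    """One row per ROI voxel, labelled by union ground-truth membership.

    The study must be preprocessed (all channels on the common ROI grid).
    """
    if not study.is_preprocessed:
        raise FeatureError("study must be preprocessed before feature assembly")
    del box  # the preprocessed study is already cropped to its ROI box
    ref = study.t2w
    nz, ny, nx = ref.data.shape
    blocks, names = [], []
    for seq in descriptor.members:
        chans = _channel_stack(study, seq)
        _check_counts(seq, chans)
        for c in chans:
            ref.require_same_grid(c)
        if seq == ph.T2W:
            block = _t2w_feature_stack(study.t2w).reshape(-1, 9)
        else:
            block = np.stack(
                [np.asarray(c.data, dtype=float).ravel() for c in chans], axis=-1
            )
        blocks.append(block)
        names.extend(_feature_names(seq, chans))
    values = np.concatenate(blocks, axis=1)
    zi, yi, xi = np.unravel_index(np.arange(nz * ny * nx), (nz, ny, nx))
    voxel_indices = np.stack([zi, yi, xi], axis=-1)
    union = ph.ground_truth_union(study.observer_a, study.observer_b)
    labels = union.data.astype(bool).ravel().astype(np.int8)
    return FeatureMatrix(
        values=values,
        voxel_indices=voxel_indices,
        labels=labels,
        patient_id=study.patient_id,
        descriptor=descriptor,
        feature_names=tuple(names),
    )


def zscore_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Z-score every feature column within the patient's ROI voxels.

    Each column is transformed to mean 0 and standard deviation 1 using
    statistics over all rows of this patient's matrix; the statistics are
    recorded so predictions reuse the same per-patient scaling.
    """
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [matrix.feature_names[i] for i in np.nonzero(sd == 0)[0]]
        raise ZeroVarianceError(
            f"zero-variance feature column(s) within patient "
            f"{matrix.patient_id}: {bad[:5]}"
        )
    values = (matrix.values - mean) / sd
    return replace(
        matrix,
        values=values,
        norm_stats={"mean": mean.copy(), "sd": sd.copy()},
    )


def undersample(matrix: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Balance the classes per patient by random undersampling.

    All tumor rows are kept; an equal number of non-tumor rows is drawn
    uniformly without replacement.  If the patient has fewer non-tumor
    than tumor voxels, all non-tumor rows are kept and a warning issued.
    """
    labels = matrix.labels
    tumor_idx = np.nonzero(labels == 1)[0]
    bg_idx = np.nonzero(labels == 0)[0]
    if tumor_idx.size == 0 or bg_idx.size == 0:
        raise FeatureError("undersampling needs both classes present")
    rng = np.random.default_rng(seed)
    if bg_idx.size < tumor_idx.size:
        warnings.warn(
            f"patient {matrix.patient_id}: fewer non-tumor ({bg_idx.size}) than "
            f"tumor ({tumor_idx.size}) voxels; keeping all non-tumor rows"
        )
        keep_bg = bg_idx
    else:
        keep_bg = rng.choice(bg_idx, size=tumor_idx.size, replace=False)
    keep = np.sort(np.concatenate([tumor_idx, keep_bg]))
    return replace(
        matrix,
        values=matrix.values[keep],
        voxel_indices=matrix.voxel_indices[keep],
        labels=labels[keep],
    )


def patient_matrix(
    study: ph.MultiSequenceStudy, descriptor: FeatureSetDescriptor
) -> FeatureMatrix:
    """Assembled and per-patient z-scored full-ROI matrix for one study."""
    return zscore_normalize(assemble_matrix(study, descriptor))
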