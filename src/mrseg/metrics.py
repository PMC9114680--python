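"""Segmentation evaluation: Dice overlap and mean symmetric surface distance.

DICE = 2|P ∩ G| / (|P| + |G|).

MSD = (Σ_i d(i, G→P) + Σ_i d(i, P→G)) / (N_G + N_P), where the sums run
over the N_G and N_P surface voxels of the ground truth G and the
prediction P, and d(i, A→B) is the minimal 3D Euclidean distance (mm)
from surface voxel i of A to any surface voxel of B.  Surfaces are the
mask voxels with at least one face-adjacent (6-connectivity) background
neighbor, the volume boundary counting as background, and distances are
measured between voxel centers in physical coordinates.

An empty prediction has DICE 0 and an undefined MSD; the record carries
an ``empty_prediction`` flag instead of a number in that case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import ImageVolume


class EmptyMaskError(ValueError):
    """A metric that needs a non-empty mask received an empty one."""


@dataclass(frozen=True)
class SurfaceVoxelSet:
    """Border voxels of a binary mask."""

    indices: np.ndarray  # (N, 3) integer (z, y, x)
    coords_mm: np.ndarray  # (N, 3) physical (x, y, z) voxel centers

    @property
    def count(self) -> int:
        return int(self.indices.shape[0])


@dataclass
class MetricsRecord:
    """Evaluation record for one (patient, algorithm, feature-set) cell."""

    patient_id: str
    algorithm: str
    features: str
    dice: float
    msd: float | None
    empty_prediction: bool = False
    extras: dict = field(default_factory=dict)


def surface_voxels(mask: ImageVolume) -> SurfaceVoxelSet:
    """Mask voxels with a 6-connected background neighbor (border = background)."""
    m = mask.data.astype(bool)
    if not m.any():
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(m, structure=structure, border_value=0)
    surf = m & ~interior
    zi, yi, xi = np.nonzero(surf)
    idx = np.stack([zi, yi, xi], axis=-1)
    sp = np.asarray(mask.spacing)
    org = np.asarray(mask.origin)
    coords = org + np.stack([xi, yi, zi], axis=-1) * sp
    return SurfaceVoxelSet(indices=idx, coords_mm=coords)


def dice(p: ImageVolume, g: ImageVolume) -> float:
    """Sørensen–Dice similarity coefficient between two masks on one grid."""
    p.require_same_grid(g)
    pm = p.data.astype(bool)
    gm = g.data.astype(bool)
    denom = pm.sum() + gm.sum()
    if denom == 0:
        raise EmptyMaskError("Dice is undefined when both masks are empty")
    return float(2.0 * np.logical_and(pm, gm).sum() / denom)


def msd(p: ImageVolume, g: ImageVolume) -> float:
    """Mean symmetric surface distance (mm) between two masks on one grid."""
    p.require_same_grid(g)
    if not p.data.astype(bool).any() or not g.data.astype(bool).any():
        raise EmptyMaskError("MSD is undefined for an empty mask")
    sp_surf = surface_voxels(p)
    sg_surf = surface_voxels(g)
    tree_p = cKDTree(sp_surf.coords_mm)
    tree_g = cKDTree(sg_surf.coords_mm)
    d_g_to_p, _ = tree_p.query(sg_surf.coords_mm)
    d_p_to_g, _ = tree_g.query(sp_surf.coords_mm)
    return float(
        (d_g_to_p.sum() + d_p_to_g.sum()) / (sg_surf.count + sp_surf.count)
    )


def evaluate_masks(
    pred: ImageVolume,
    gt: ImageVolume,
    patient_id: str = "",
    algorithm: str = "",
    features: str = "",
) -> MetricsRecord:
    """DICE and MSD of a prediction against the ground truth, with the
    empty-prediction case flagged rather than scored."""
    if not gt.data.astype(bool).any():
        raise EmptyMaskError("ground truth mask is empty")
    if not pred.data.astype(bool).any():
        return MetricsRecord(
            patient_id=patient_id, algorithm=algorithm, features=features,
            dice=0.0, msd=None, empty_prediction=True,
        )
    return MetricsRecord(
        patient_id=patient_id, algorithm=algorithm, features=features,
        dice=dice(pred, gt), msd=msd(pred, gt),
    )


def interobserver(a: ImageVolume, b: ImageVolume, patient_id: str = "") -> MetricsRecord:
    """Agreement between two observer delineations (DICE and MSD)."""
    return evaluate_masks(
        a, b, patient_id=patient_id, algorithm="observer", features="interobserver"
    )
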