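"""Semi-automatic post-processing of the raw voxelwise prediction.

The chain is: (1) a 3D median filter smooths the predicted mask,
(2) a watershed on the negated Euclidean distance transform splits the
mask into connected regions (markers are the regional maxima of the
distance transform after h-maxima suppression), (3) one seed voxel per
axial slice is sampled uniformly inside the ground-truth delineation —
standing in for a user's mouse clicks — and (4) only the regions hit by
at least one seed are kept.

All operations act in 3D with 26-connectivity; the median kernel and the
h-maxima depth are configurable.  A seed that lands on a watershed line
is snapped to the nearest labeled voxel within 1 mm, otherwise ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .volume import ImageVolume

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class RegionLabelMap:
    """Connected-region labels (0 = background) over the smoothed mask."""

    labels: ImageVolume  # integer data
    n_regions: int
    region_sizes: dict[int, int]


@dataclass(frozen=True)
class SeedSet:
    """One simulated click per axial ground-truth slice."""

    voxels: tuple[tuple[int, int, int], ...]  # (z, y, x)
    seed: int


@dataclass
class SegmentationResult:
    """Raw and post-processed prediction for one patient."""

    patient_id: str
    raw_mask: ImageVolume
    post_mask: ImageVolume | None = None
    seeds: SeedSet | None = None
    intermediates: dict = field(default_factory=dict)


def median_smooth(mask: ImageVolume, radius: int = 1) -> ImageVolume:
    """3D median filter with a (2r+1)^3 kernel on a binary mask."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    m = mask.data.astype(bool)
    if radius == 0:
        return mask.with_data(m.copy())
    size = 2 * radius + 1
    out = ndimage.median_filter(m.astype(np.uint8), size=size, mode="constant", cval=0)
    return mask.with_data(out.astype(bool))


def split_regions(mask: ImageVolume, h_mm: float = 1.0) -> RegionLabelMap:
    """Split a mask into regions by watershed on its distance transform.

    The Euclidean distance transform (mm) is computed inside the mask,
    markers are placed at its regional maxima after suppressing maxima
    shallower than ``h_mm``, and the watershed of the negated distance
    map separates touching regions; any connected component left without
    a marker receives one at its deepest voxel so the labeled voxels
    always tile the input mask.  Labels are relabeled contiguously 1..K.
    """
    m = mask.data.astype(bool)
    empty = mask.with_data(np.zeros(m.shape, dtype=np.int32))
    if not m.any():
        return RegionLabelMap(labels=empty, n_regions=0, region_sizes={})
    sampling = mask.spacing[::-1]  # (sz, sy, sx)
    dist = ndimage.distance_transform_edt(m, sampling=sampling)
    peaks = h_maxima(dist, h_mm) & m
    markers, _ = ndimage.label(peaks, structure=_CONN26)
    # guarantee a marker in every connected component
    comps, n_comp = ndimage.label(m, structure=_CONN26)
    next_label = int(markers.max())
    for c in range(1, n_comp + 1):
        sel = comps == c
        if not markers[sel].any():
            flat = np.argmax(np.where(sel, dist, -1.0))
            next_label += 1
            markers[np.unravel_index(flat, m.shape)] = next_label
    labels = watershed(-dist, markers=markers, mask=m, connectivity=_CONN26)
    # contiguous relabel 1..K
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1)
    labels = lut[labels]
    sizes = {
        int(k): int(v)
        for k, v in zip(*np.unique(labels[labels > 0], return_counts=True))
    }
    return RegionLabelMap(
        labels=mask.with_data(labels), n_regions=len(sizes), region_sizes=sizes
    )


def simulate_seeds(gt: ImageVolume, seed: int) -> SeedSet:
    """Sample one voxel per axial slice uniformly within the ground truth."""
    m = gt.data.astype(bool)
    if not m.any():
        raise ValueError("cannot place seeds in an empty ground truth")
    rng = np.random.default_rng(seed)
    voxels = []
    for z in range(m.shape[0]):
        ys, xs = np.nonzero(m[z])
        if ys.size == 0:
            continue
        k = int(rng.integers(0, ys.size))
        voxels.append((z, int(ys[k]), int(xs[k])))
    return SeedSet(voxels=tuple(voxels), seed=int(seed))


def select_regions(
    labels: RegionLabelMap, seeds: SeedSet, snap_mm: float = 1.0
) -> ImageVolume:
    """Union of the watershed regions containing at least one seed.

    Seeds on background are snapped to the nearest labeled voxel within
    ``snap_mm`` (they may sit on a watershed line), otherwise they select
    nothing.  An empty result is allowed.
    """
    lab = labels.labels.data
    vol = labels.labels
    if lab.max() == 0:
        return vol.with_data(np.zeros(lab.shape, dtype=bool))
    dist, (iz, iy, ix) = ndimage.distance_transform_edt(
        lab == 0, sampling=vol.spacing[::-1], return_indices=True
    )
    hit: set[int] = set()
    for z, y, x in seeds.voxels:
        value = int(lab[z, y, x])
        if value == 0:
            if dist[z, y, x] <= snap_mm:
                value = int(lab[iz[z, y, x], iy[z, y, x], ix[z, y, x]])
            else:
                continue
        if value > 0:
            hit.add(value)
    keep = np.isin(lab, sorted(hit)) if hit else np.zeros(lab.shape, dtype=bool)
    return vol.with_data(keep)


def postprocess(
    pred: ImageVolume,
    gt: ImageVolume,
    seed: int,
    median_radius: int = 1,
    h_mm: float = 1.0,
    snap_mm: float = 1.0,
    patient_id: str = "",
) -> SegmentationResult:
    """Full semi-automatic chain: smooth, split, seed, select.

    All intermediates (smoothed mask, label map, seeds) are retained in
    the result; the final mask is always a subset of the smoothed mask.
    """
    pred.require_same_grid(gt)
    smoothed = median_smooth(pred, radius=median_radius)
    regions = split_regions(smoothed, h_mm=h_mm)
    seeds = simulate_seeds(gt, seed)
    final = select_regions(regions, seeds, snap_mm=snap_mm)
    return SegmentationResult(
        patient_id=patient_id or getattr(pred, "patient_id", ""),
        raw_mask=pred,
        post_mask=final,
        seeds=seeds,
        intermediates={"smoothed": smoothed, "regions": regions},
    )
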