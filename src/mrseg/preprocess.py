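"""Preprocessing: dynamic time-point selection, rigid registration and
resampling to a common isotropic grid, and cropping to a tumor-centred
region of interest.

The dynamic contrast series is reduced to 14 frames that normalise the
temporal sampling between patients: starting at contrast arrival, the
eight frames closest to a 4 s temporal resolution, followed by six frames
at 80 s resolution (nominal times arrival + 0, 4, ..., 28, 108, 188, ...,
508 s).  All sequences are then rigidly registered to the T2w reference
and resampled onto a 1 mm isotropic grid restricted to a cuboid box with
a 20 mm margin around the union of the two observer delineations,
clipped to the field of view common to all sequences.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from . import phantom as ph
from .volume import ImageVolume, as_bool_mask


class SelectionError(ValueError):
    """The dynamic series cannot supply the required 14 frames."""


class RegistrationError(RuntimeError):
    """Rigid registration failed for one sequence."""

    def __init__(self, sequence: str, message: str):
        self.sequence = sequence
        super().__init__(f"registration failed for {sequence}: {message}")


# nominal offsets (s) of the 14 selected frames relative to contrast arrival
FAST_PHASE_OFFSETS = tuple(4.0 * k for k in range(8))  # 0..28 s
SLOW_PHASE_OFFSETS = tuple(28.0 + 80.0 * k for k in range(1, 7))  # 108..508 s
NOMINAL_OFFSETS = FAST_PHASE_OFFSETS + SLOW_PHASE_OFFSETS


@dataclass(frozen=True)
class TimepointSelection:
    """The 14 dynamic frames chosen for feature extraction."""

    indices: tuple[int, ...]
    timestamps_s: tuple[float, ...]
    arrival_s: float

    def __post_init__(self):
        if len(self.indices) != 14:
            raise SelectionError(f"expected 14 frames, got {len(self.indices)}")
        if np.any(np.diff(self.timestamps_s) < 0):
            raise SelectionError("selected timestamps must be non-decreasing")


def select_dme_timepoints(
    timestamps: "list[float] | np.ndarray", arrival: float
) -> TimepointSelection:
    """Pick the 14 dynamic frames nearest the nominal two-phase schedule.

    For each nominal target (arrival + 0, 4, ..., 28 s, then + 108, 188,
    ..., 508 s) the acquisition frame with the closest timestamp is
    selected; ties break toward the earlier frame, and a frame already
    selected for an earlier target is skipped in favour of the next
    nearest unused frame.
    """
    ts = np.asarray(timestamps, dtype=float)
    if ts.ndim != 1 or ts.size == 0:
        raise SelectionError("timestamps must be a non-empty 1D sequence")
    if np.any(np.diff(ts) <= 0):
        raise SelectionError("timestamps must be strictly increasing")
    if arrival > ts[-1]:
        raise SelectionError(
            f"contrast arrival {arrival} s is after the last frame {ts[-1]} s"
        )
    if ts[-1] < arrival + NOMINAL_OFFSETS[-1]:
        raise SelectionError(
            f"acquisition ends at {ts[-1]} s; frames are required up to "
            f"{arrival + NOMINAL_OFFSETS[-1]} s after arrival"
        )
    if ts.size < len(NOMINAL_OFFSETS):
        raise SelectionError(
            f"need at least {len(NOMINAL_OFFSETS)} frames, have {ts.size}"
        )

    used: set[int] = set()
    chosen: list[int] = []
    for off in NOMINAL_OFFSETS:
        target = arrival + off
        # stable order: distance, then earlier timestamp
        order = sorted(range(ts.size), key=lambda i: (abs(ts[i] - target), ts[i]))
        idx = next((i for i in order if i not in used), None)
        if idx is None:
            raise SelectionError("fewer than 14 distinct selectable frames")
        used.add(idx)
        chosen.append(idx)
    chosen.sort()
    return TimepointSelection(
        indices=tuple(chosen),
        timestamps_s=tuple(ts[chosen]),
        arrival_s=float(arrival),
    )


# ---------------------------------------------------------------------
# region of interest
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned cuboid in physical space (mm), closed in mm.

    The associated analysis grid is isotropic with ``spacing`` mm voxels;
    voxel index ranges are half-open, with voxel centers at
    ``lower + (i + 1/2) * spacing``.
    """

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]
    spacing: float = 1.0

    def __post_init__(self):
        lo, hi = np.asarray(self.lower), np.asarray(self.upper)
        if np.any(hi <= lo):
            raise ValueError(f"degenerate box: lower {self.lower}, upper {self.upper}")

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        n = np.ceil(
            (np.asarray(self.upper) - np.asarray(self.lower)) / self.spacing - 1e-9
        ).astype(int)
        return tuple(int(v) for v in n)

    @property
    def grid_origin(self) -> tuple[float, float, float]:
        return tuple(float(l) + self.spacing / 2 for l in self.lower)

    def intersect(self, other: "RoiBox") -> "RoiBox":
        lo = np.maximum(self.lower, other.lower)
        hi = np.minimum(self.upper, other.upper)
        if np.any(hi <= lo):
            raise ValueError("boxes do not intersect")
        return RoiBox(tuple(lo), tuple(hi), self.spacing)

    def empty_volume(self, dtype=float, **channel) -> ImageVolume:
        nx, ny, nz = self.shape_xyz
        return ImageVolume(
            data=np.zeros((nz, ny, nx), dtype=dtype),
            spacing=(self.spacing,) * 3,
            origin=self.grid_origin,
            channel=channel,
        )


def common_fov(study: ph.MultiSequenceStudy) -> RoiBox:
    """The physical field of view present in all sequences of a study."""
    lows, highs = [], []
    for seq in ph.SEQUENCES:
        chans = study.channels(seq)
        if not chans:
            continue
        lo, hi = chans[0].extent()
        lows.append(lo)
        highs.append(hi)
    lo = np.max(np.stack(lows), axis=0)
    hi = np.min(np.stack(highs), axis=0)
    return RoiBox(tuple(lo), tuple(hi))


def compute_bounding_box(
    union_mask: ImageVolume, margin_mm: float = 20.0, fov: RoiBox | None = None
) -> RoiBox:
    """Cuboid box with a margin around a delineation, clipped to the FOV.

    The tight box spans the voxel centers of the mask; each face is then
    pushed outward by ``margin_mm`` and the result intersected with
    ``fov`` when given.
    """
    m = union_mask.data.astype(bool)
    if not m.any():
        raise ValueError("union mask is empty")
    zi, yi, xi = np.nonzero(m)
    sp = np.asarray(union_mask.spacing)
    org = np.asarray(union_mask.origin)
    idx = np.stack([xi, yi, zi], axis=-1)
    lo = org + idx.min(axis=0) * sp - margin_mm
    hi = org + idx.max(axis=0) * sp + margin_mm
    box = RoiBox(tuple(lo), tuple(hi))
    if fov is not None:
        try:
            box = box.intersect(RoiBox(fov.lower, fov.upper))
        except ValueError as exc:
            raise ValueError("bounding box lies outside the common FOV") from exc
    return box


# ---------------------------------------------------------------------
# registration and resampling
# ---------------------------------------------------------------------

def _box_mask_on(volume: ImageVolume, box: RoiBox) -> sitk.Image:
    centers = volume.voxel_centers()
    inside = np.all(
        (centers >= np.asarray(box.lower)) & (centers <= np.asarray(box.upper)),
        axis=-1,
    )
    img = volume.with_data(inside.astype(np.uint8)).to_sitk()
    return sitk.Cast(img, sitk.sitkUInt8)


def _estimate_rigid(
    fixed: ImageVolume,
    moving: ImageVolume,
    box: RoiBox,
    sequence: str,
    sampling_seed: int = 1234,
) -> sitk.Euler3DTransform:
    """Rigid (6-DOF) mutual-information registration, T2w fixed."""
    fixed_img = sitk.Cast(fixed.to_sitk(), sitk.sitkFloat64)
    moving_img = sitk.Cast(moving.to_sitk(), sitk.sitkFloat64)
    initial = sitk.CenteredTransformInitializer(
        fixed_img, moving_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.5, sampling_seed)
    reg.SetMetricFixedMask(_box_mask_on(fixed, box))
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    reg.SetInitialTransform(sitk.Euler3DTransform(initial), inPlace=False)
    try:
        result = reg.Execute(fixed_img, moving_img)
    except RuntimeError as exc:  # pragma: no cover - ITK failure path
        raise RegistrationError(sequence, str(exc)) from exc
    result = result.Downcast()
    if isinstance(result, sitk.CompositeTransform):
        result = result.GetNthTransform(0).Downcast()
    if not isinstance(result, sitk.Euler3DTransform):  # pragma: no cover
        raise RegistrationError(sequence, f"unexpected transform {type(result)}")
    return result


def _resample_to_box(
    volume: ImageVolume,
    box: RoiBox,
    transform: sitk.Transform | None,
    nearest: bool = False,
) -> ImageVolume:
    img = volume.to_sitk()
    if nearest:
        img = sitk.Cast(img, sitk.sitkUInt8)
        interp = sitk.sitkNearestNeighbor
        default = 0.0
    else:
        img = sitk.Cast(img, sitk.sitkFloat64)
        interp = sitk.sitkLinear
        default = float(np.asarray(volume.data, dtype=float).mean())
    nx, ny, nz = box.shape_xyz
    out = sitk.Resample(
        img,
        (nx, ny, nz),
        transform or sitk.Transform(),
        interp,
        box.grid_origin,
        (box.spacing,) * 3,
        (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        default,
    )
    res = ImageVolume.from_sitk(out, **volume.channel)
    if nearest:
        res.data = res.data.astype(bool)
    return res


def register_and_resample(
    study: ph.MultiSequenceStudy,
    box: RoiBox,
    estimate_transforms: bool = True,
    sampling_seed: int = 1234,
) -> ph.MultiSequenceStudy:
    """Register every sequence to the T2w reference and resample onto the
    ROI's 1 mm isotropic grid.

    One rigid transform is estimated per sequence from a representative
    channel (b = 0 for DW, the shortest echo for T2*w, the first frame
    for the dynamic series) and applied to all channels of that sequence;
    masks are resampled with nearest-neighbor interpolation, images with
    linear interpolation.  With ``estimate_transforms=False`` the
    sequences are assumed aligned and only resampled.
    """
    transforms: dict[str, sitk.Transform | None] = {ph.T2W: None}
    if estimate_transforms:
        # representative channel per sequence: the one with the strongest
        # tissue contrast (longest echo, highest diffusion weighting)
        representatives = {
            ph.T2SW: max(study.t2sw, key=lambda v: v.channel["te_ms"]),
            ph.DW: max(study.dw, key=lambda v: v.channel["b"]),
            ph.DME: max(study.dme[0], key=lambda v: v.channel["te_ms"]),
        }
        for seq, rep in representatives.items():
            transforms[seq] = _estimate_rigid(
                study.t2w, rep, box, seq, sampling_seed=sampling_seed
            )
    else:
        transforms.update({ph.T2SW: None, ph.DW: None, ph.DME: None})

    out = copy.copy(study)
    out.t2w = _resample_to_box(study.t2w, box, transforms[ph.T2W])
    out.t2sw = [_resample_to_box(v, box, transforms[ph.T2SW]) for v in study.t2sw]
    out.dw = [_resample_to_box(v, box, transforms[ph.DW]) for v in study.dw]
    out.dme = [
        [_resample_to_box(v, box, transforms[ph.DME]) for v in frame]
        for frame in study.dme
    ]
    for attr in ("observer_a", "observer_b", "truth"):
        setattr(out, attr, as_bool_mask(
            _resample_to_box(getattr(study, attr), box, None, nearest=True)
        ))
    out.is_preprocessed = True
    out.roi_box = box
    out._estimated_transforms = transforms  # kept for inspection/logging
    return out


def preprocess_study(
    study: ph.MultiSequenceStudy,
    margin_mm: float = 20.0,
    estimate_transforms: bool = True,
    sampling_seed: int = 1234,
) -> ph.MultiSequenceStudy:
    """Full preprocessing chain for one study.

    Selects the 14 dynamic frames, computes the ROI box (margin around
    the union delineation, clipped to the common FOV), registers and
    resamples all channels onto the 1 mm ROI grid.  Only the selected
    dynamic frames are resampled.
    """
    selection = select_dme_timepoints(study.timestamps_s, study.arrival_s)
    union = ph.ground_truth_union(study.observer_a, study.observer_b)
    box = compute_bounding_box(union, margin_mm=margin_mm, fov=common_fov(study))
    trimmed = copy.copy(study)
    trimmed.dme = [study.dme[i] for i in selection.indices]
    trimmed.timestamps_s = selection.timestamps_s
    out = register_and_resample(
        trimmed, box,
        estimate_transforms=estimate_transforms,
        sampling_seed=sampling_seed,
    )
    out.dme_selection = selection
    return out
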