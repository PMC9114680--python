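"""Lightweight 3D image container with physical geometry.

Arrays are stored in (z, y, x) index order while all physical metadata
(spacing, origin, coordinates) uses (x, y, z) order, matching the
SimpleITK convention.  The origin is the physical position (mm) of the
center of voxel (0, 0, 0); voxel centers lie at ``origin + index * spacing``.
All volumes produced by this package use an identity direction matrix;
rigid misalignment between sequences is expressed through transforms,
not through oblique grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import SimpleITK as sitk

IDENTITY_DIRECTION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class ImageVolume:
    """A scalar 3D volume on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values, z slowest.
    spacing : tuple of float
        Voxel spacing (sx, sy, sz) in mm.
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0), (x, y, z).
    channel : dict
        Free-form channel tag, e.g. ``{"sequence": "DW", "b": 1000.0}``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")

    # -- geometry -----------------------------------------------------

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    def voxel_centers(self) -> np.ndarray:
        """Physical centers of all voxels, shape (nz, ny, nx, 3) in (x, y, z) mm."""
        nz, ny, nx = self.data.shape
        zi, yi, xi = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        return np.stack(
            [ox + xi * sx, oy + yi * sy, oz + zi * sz], axis=-1
        ).astype(float)

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical field of view (lower, upper) in mm, including voxel extents."""
        sp = np.asarray(self.spacing)
        lo = np.asarray(self.origin) - 0.5 * sp
        hi = np.asarray(self.origin) + (np.asarray(self.shape_xyz) - 0.5) * sp
        return lo, hi

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "ImageVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: shape {self.data.shape}/{other.data.shape}, "
                f"spacing {self.spacing}/{other.spacing}, "
                f"origin {self.origin}/{other.origin}"
            )

    def with_data(self, data: np.ndarray, **channel: Any) -> "ImageVolume":
        """A new volume on the same grid with different voxel values."""
        vol = replace(self, data=data)
        if channel:
            vol.channel = {**self.channel, **channel}
        return vol

    # -- SimpleITK bridge ---------------------------------------------

    def to_sitk(self) -> sitk.Image:
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        img = sitk.GetImageFromArray(np.ascontiguousarray(data))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(IDENTITY_DIRECTION)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, **channel: Any) -> "ImageVolume":
        if not np.allclose(img.GetDirection(), IDENTITY_DIRECTION, atol=1e-6):
            raise ValueError("only identity-direction volumes are supported")
        return cls(
            data=sitk.GetArrayFromImage(img),
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            channel=dict(channel),
        )


def as_bool_mask(vol: ImageVolume) -> ImageVolume:
    return vol.with_data(vol.data.astype(bool))


def mask_volume_mm3(mask: ImageVolume) -> float:
    """Total physical volume of a binary mask in mm^3."""
    return float(np.count_nonzero(mask.data)) * float(np.prod(mask.spacing))
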