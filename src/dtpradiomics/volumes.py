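"""3D image volumes: NIfTI I/O, resampling and sphere voxelization.

Volumes are axis-aligned scalar grids with voxel-center world coordinates
``world = origin + index * spacing`` (mm).  Masks travel on the exact grid of
their companion volume; grid mismatches are hard errors, never silently
resampled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk


class UnitTag(str, enum.Enum):
    """Physical interpretation of voxel values."""

    SUV = "SUV"
    ACTIVITY = "ACTIVITY"
    KI_SCALED = "KI_SCALED"  # 100 * Ki, SUV-comparable scale
    KI_RAW = "KI_RAW"        # Ki in 1/min (internal, pre-scaling)
    MASK = "MASK"


class ResampleMode(str, enum.Enum):
    LINEAR = "linear"
    NEAREST = "nearest"


@dataclass
class ImageVolume:
    """A 3D scalar grid with spacing/origin metadata.

    Parameters
    ----------
    data
        3D array (float for intensity volumes, 0/1 for masks).
    spacing
        Voxel size in mm per axis.
    origin
        World coordinates (mm) of the center of voxel (0, 0, 0).
    unit_tag
        What the voxel values mean (SUV, activity, scaled Ki, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit_tag: UnitTag = UnitTag.SUV

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"expected 3D volume, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if not all(np.isfinite(self.spacing)) or min(self.spacing) <= 0:
            raise ValueError(f"non-positive or non-finite spacing {self.spacing}")
        self.unit_tag = UnitTag(self.unit_tag)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge-to-edge physical extent (mm): (low corner, high corner)."""
        o = np.asarray(self.origin)
        s = np.asarray(self.spacing)
        n = np.asarray(self.shape)
        return o - s / 2.0, o - s / 2.0 + n * s

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_data(self, data: np.ndarray, unit_tag: UnitTag | None = None) -> "ImageVolume":
        return replace(self, data=data, unit_tag=unit_tag or self.unit_tag)


def _affine(volume: ImageVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = volume.spacing
    aff[:3, 3] = volume.origin
    return aff


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume to NIfTI (.nii/.nii.gz), float64 data preserved."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), _affine(volume))
    img.header.set_zooms(volume.spacing)
    img.header["descrip"] = volume.unit_tag.value.encode()[:79]
    nib.save(img, str(path))


def read_volume(path: str | Path, unit_tag: UnitTag | None = None) -> ImageVolume:
    """Read a 3D NIfTI volume.

    The unit tag is taken from the header description if it matches a known
    tag, unless overridden by the caller.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not all(np.isfinite(zooms)) or min(zooms) <= 0:
        raise ValueError(f"non-finite or non-positive voxel spacing in {path}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if unit_tag is None:
        descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
        try:
            unit_tag = UnitTag(descrip)
        except ValueError:
            unit_tag = UnitTag.SUV
    return ImageVolume(data=data, spacing=zooms, origin=origin, unit_tag=unit_tag)


def resample_volume(
    volume: ImageVolume,
    target_mm: float,
    mode: ResampleMode | str = ResampleMode.LINEAR,
) -> ImageVolume:
    """Resample to an isotropic grid of ``target_mm`` voxels.

    Physical edge-to-edge extent is preserved within one voxel; the new grid
    is edge-aligned with the old one.  Intensity volumes use linear
    interpolation, masks must use nearest so labels stay binary.
    """
    if not np.isfinite(target_mm) or target_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_mm}")
    mode = ResampleMode(mode)
    if volume.data.size == 0:
        raise ValueError("empty volume")

    old_spacing = np.asarray(volume.spacing)
    old_shape = np.asarray(volume.shape)
    if np.allclose(old_spacing, target_mm):
        return replace(volume, data=volume.data.copy())

    new_shape = np.maximum(1, np.round(old_shape * old_spacing / target_mm).astype(int))
    # voxel-center origin shift keeping physical edges aligned
    new_origin = np.asarray(volume.origin) - old_spacing / 2.0 + target_mm / 2.0

    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))

    interp = sitk.sitkLinear if mode is ResampleMode.LINEAR else sitk.sitkNearestNeighbor
    res = sitk.Resample(
        img,
        [int(n) for n in new_shape],
        sitk.Transform(),
        interp,
        tuple(float(o) for o in new_origin),
        (float(target_mm),) * 3,
        (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        0.0,
        sitk.sitkFloat64,
    )
    out = sitk.GetArrayFromImage(res).transpose(2, 1, 0)
    if mode is ResampleMode.NEAREST:
        out = np.round(out)
    return ImageVolume(
        data=out,
        spacing=(target_mm,) * 3,
        origin=tuple(new_origin),
        unit_tag=volume.unit_tag,
    )


def sphere_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    center_mm: tuple[float, float, float],
    radius_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose center lies within ``radius_mm`` of a point."""
    if radius_mm <= 0:
        raise ValueError("sphere radius must be positive")
    grids = np.meshgrid(
        *[origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)],
        indexing="ij",
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return d2 <= radius_mm**2
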