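"""Lesion VOI definition on SUV images and transfer to Ki maps.

The VOI is the set of voxels at or above 30% of the regional maximum SUV,
restricted to the 26-connected component containing the maximum voxel.  The
maximum is taken within the caller's seed region (a bounding box), not the
whole volume, so multiple lesions per study segment independently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume

_CONN26 = np.ones((3, 3, 3), dtype=int)


class VoiSource(str, enum.Enum):
    SUV_THRESHOLD = "SUV_THRESHOLD"
    TRANSFERRED = "TRANSFERRED"
    USER = "USER"


@dataclass
class VOI:
    """Binary lesion mask on the grid of a named companion volume."""

    mask: np.ndarray
    source: VoiSource = VoiSource.USER
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("VOI mask must be 3D")
        if not self.mask.any():
            raise ValueError("empty VOI: mask must contain at least one voxel")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _region_mask(shape, bbox) -> np.ndarray:
    region = np.zeros(shape, dtype=bool)
    (x0, y0, z0), (x1, y1, z1) = bbox
    if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1] and 0 <= z0 < z1 <= shape[2]):
        raise ValueError(f"bounding box {bbox} outside grid {shape} or empty")
    region[x0:x1, y0:y1, z0:z1] = True
    return region


def threshold_segment(
    suv: ImageVolume,
    bbox: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None,
    fraction: float = 0.30,
    seed_point: tuple[int, int, int] | None = None,
) -> VOI:
    """Fixed-fraction-of-maximum thresholding within a seed region.

    Keeps voxels with SUV >= fraction * max(SUV in region), then restricts to
    the 26-connected suprathreshold component containing the regional maximum
    (or the component containing ``seed_point``, if given and suprathreshold).
    """
    if not (0 < fraction < 1):
        raise ValueError(f"threshold fraction must be in (0, 1), got {fraction}")
    region = _region_mask(suv.shape, bbox) if bbox is not None else np.ones(suv.shape, bool)
    if not region.any():
        raise ValueError("empty seed region")
    vals = np.where(region, suv.data, -np.inf)
    vmax = float(vals.max())
    if vmax <= 0:
        raise ValueError("all-zero (or non-positive) seed region: cannot threshold")
    above = region & (suv.data >= fraction * vmax)
    labels, _ = ndimage.label(above, structure=_CONN26)
    if seed_point is not None and above[tuple(seed_point)]:
        keep = labels[tuple(seed_point)]
    else:
        keep = labels[np.unravel_index(int(np.argmax(vals)), suv.shape)]
    mask = labels == keep
    return VOI(
        mask=mask,
        source=VoiSource.SUV_THRESHOLD,
        provenance={"fraction": fraction, "regional_max": vmax, "bbox": bbox},
    )


def transfer_voi(
    voi: VOI,
    ki: ImageVolume,
    add_voxels: list[tuple[int, int, int]] | None = None,
    remove_voxels: list[tuple[int, int, int]] | None = None,
) -> VOI:
    """Copy a VOI onto a Ki map grid, with optional deterministic edits.

    Additions are applied before removals; a voxel outside the grid is a
    hard error, as is an edit sequence that empties the VOI.
    """
    if voi.mask.shape != ki.shape:
        raise ValueError(
            f"VOI grid {voi.mask.shape} does not match Ki grid {ki.shape}"
        )
    mask = voi.mask.copy()
    for vox in add_voxels or []:
        if not all(0 <= v < s for v, s in zip(vox, mask.shape)):
            raise ValueError(f"edit voxel {vox} outside grid {mask.shape}")
        mask[tuple(vox)] = True
    for vox in remove_voxels or []:
        if not all(0 <= v < s for v, s in zip(vox, mask.shape)):
            raise ValueError(f"edit voxel {vox} outside grid {mask.shape}")
        mask[tuple(vox)] = False
    if not mask.any():
        raise ValueError("empty VOI after edits")
    return VOI(
        mask=mask,
        source=VoiSource.TRANSFERRED,
        provenance={
            "added": list(map(tuple, add_voxels or [])),
            "removed": list(map(tuple, remove_voxels or [])),
            "parent": voi.source.value,
        },
    )
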