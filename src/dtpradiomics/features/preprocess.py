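"""Intensity discretization and resampling ahead of feature computation.

Volumes are resampled to an isotropic grid (4 mm default; linear for
intensities, nearest for the mask) and discretized with an absolute-bound
rule: ``bin_count`` bins spanning a fixed [min, max] intensity window
(64 bins over [0, 20] by default — so the bin width is 20/64 = 0.3125).
Values at or below the window floor land in bin 1 (this is where negative
scaled-Ki voxels are clamped), values at or above the ceiling in the top
bin.  Because the bounds are absolute rather than lesion-relative, adding a
constant to the image changes the features — deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..config import PipelineConfig
from ..segmentation import VOI, VoiSource
from ..volumes import ImageVolume, ResampleMode, UnitTag, resample_volume


@dataclass
class DiscretizedVolume:
    """Gray-level volume (1..bin_count inside the VOI, 0 outside) plus the
    resampled continuous volume for the conventional indices."""

    levels: np.ndarray          # int array, 0 outside VOI
    mask: np.ndarray            # bool, the resampled VOI
    bin_count: int
    bounds: tuple[float, float]
    continuous: np.ndarray      # resampled continuous intensities (full grid)
    spacing: tuple[float, float, float]
    source_unit: UnitTag

    @property
    def bin_width(self) -> float:
        lo, hi = self.bounds
        return (hi - lo) / self.bin_count

    def bin_centers_volume(self) -> np.ndarray:
        """Continuous surrogate with every voxel at its bin-center value."""
        lo, _ = self.bounds
        return lo + (self.levels - 0.5) * self.bin_width

    def voxel_values(self) -> np.ndarray:
        return self.continuous[self.mask]

    def level_values(self) -> np.ndarray:
        return self.levels[self.mask]


def bin_index(x, bin_count: int, lo: float, hi: float) -> np.ndarray:
    """Absolute-bound bin assignment: floor((x-lo)/(hi-lo)*N)+1, clamped to
    [1, N]; x <= lo maps to 1, x >= hi maps to N."""
    x = np.asarray(x, dtype=float)
    idx = np.floor((x - lo) / (hi - lo) * bin_count).astype(int) + 1
    return np.clip(idx, 1, bin_count)


def preprocess(vol: ImageVolume, voi: VOI, cfg: PipelineConfig) -> DiscretizedVolume:
    """Resample volume+VOI to the working grid and discretize inside the VOI.

    The intensity volume must carry its proper unit tag — SUV images the SUV
    tag, Ki maps the KI_SCALED tag (i.e. already multiplied by 100 so they
    share the SUV discretization window).
    """
    if vol.unit_tag not in (UnitTag.SUV, UnitTag.KI_SCALED):
        raise ValueError(
            f"feature extraction expects SUV or KI_SCALED input, got {vol.unit_tag}"
        )
    if voi.mask.shape != vol.shape:
        raise ValueError("VOI grid does not match volume grid")

    res_vol = resample_volume(vol, cfg.resample_mm, ResampleMode.LINEAR)
    mask_vol = ImageVolume(
        data=voi.mask.astype(np.float64),
        spacing=vol.spacing,
        origin=vol.origin,
        unit_tag=UnitTag.MASK,
    )
    res_mask = resample_volume(mask_vol, cfg.resample_mm, ResampleMode.NEAREST)
    mask = res_mask.data > 0.5
    if not mask.any():
        raise ValueError("VOI is empty after resampling to the working grid")

    levels = np.zeros(res_vol.shape, dtype=np.int32)
    levels[mask] = bin_index(
        res_vol.data[mask], cfg.bin_count, cfg.intensity_min, cfg.intensity_max
    )
    return DiscretizedVolume(
        levels=levels,
        mask=mask,
        bin_count=cfg.bin_count,
        bounds=(cfg.intensity_min, cfg.intensity_max),
        continuous=res_vol.data,
        spacing=res_vol.spacing,
        source_unit=vol.unit_tag,
    )
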