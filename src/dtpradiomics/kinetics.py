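"""Dual-time-point Patlak Ki computation.

Under the irreversible two-compartment (Patlak) regime the tissue
concentration obeys

    C_PET(t) = Ki * int_0^t Cp(tau) dtau + V * Cp(t),

so with just two static time points t1 < t2 the net influx rate is the
two-point slope in Patlak coordinates:

    Ki = [C(t2)/Cp(t2) - C(t1)/Cp(t1)]
         / [I(t2)/Cp(t2) - I(t1)/Cp(t1)],      I(t) = int_0^t Cp.

The plasma curve is a population shape scaled to the patient's image-derived
blood-pool activity at t1 (mean of a 15 mm left-ventricle sphere and a 10 mm
left-atrium sphere, averaged with equal weight).  Because Ki is a ratio of
ratios it is invariant to any common rescaling of tissue and plasma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .input_function import InputFunction
from .volumes import ImageVolume, UnitTag, sphere_mask

KI_DISPLAY_SCALE = 100.0  # Ki maps are multiplied by 100 for SUV-comparable range


@dataclass(frozen=True)
class TimePair:
    """Acquisition times of the static (t1) and delayed (t2) scans, minutes."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not (self.t2 > self.t1 > 0):
            raise ValueError(f"need t2 > t1 > 0, got t1={self.t1}, t2={self.t2}")


def _sphere_mean(volume: ImageVolume, center_mm, diameter_mm: float) -> float:
    radius = diameter_mm / 2.0
    lo, hi = volume.world_extent()
    center = np.asarray(center_mm, dtype=float)
    if np.any(center - radius < lo) or np.any(center + radius > hi):
        raise ValueError(
            f"blood-pool sphere (center {tuple(center)}, diameter {diameter_mm} mm) "
            "exits the field of view"
        )
    mask = sphere_mask(volume.shape, volume.spacing, volume.origin, center, radius)
    if not mask.any():
        raise ValueError("blood-pool sphere contains no voxel centers after voxelization")
    return float(volume.data[mask].mean())


def blood_pool_activity(
    suv_t1: ImageVolume,
    lv_center_mm,
    la_center_mm,
    lv_diameter_mm: float = 15.0,
    la_diameter_mm: float = 10.0,
) -> float:
    """Image-derived blood-pool activity at t1.

    Mean SUV over a 15 mm-diameter left-ventricle sphere and a 10 mm-diameter
    left-atrium sphere, averaged with equal weight.
    """
    lv = _sphere_mean(suv_t1, lv_center_mm, lv_diameter_mm)
    la = _sphere_mean(suv_t1, la_center_mm, la_diameter_mm)
    return 0.5 * (lv + la)


def scale_input_function(
    if_pop: InputFunction, blood_suv_t1: float, t1_min: float
) -> InputFunction:
    """Scale the population input function so that Cp(t1) equals the
    patient's blood-pool activity.  The shape is unchanged."""
    if blood_suv_t1 <= 0:
        raise ValueError(f"blood-pool activity must be positive, got {blood_suv_t1}")
    pop_value = if_pop.value(t1_min)
    if pop_value <= 0:
        raise ValueError(f"population input function vanishes at t1={t1_min} min")
    return if_pop.with_scale(if_pop.scale * blood_suv_t1 / pop_value)


def patlak_denominator(if_: InputFunction, times: TimePair) -> float:
    cp1, cp2 = if_.value(times.t1), if_.value(times.t2)
    if cp1 <= 0 or cp2 <= 0:
        raise ValueError("Cp must be positive at both acquisition times")
    return if_.integral(times.t2) / cp2 - if_.integral(times.t1) / cp1


def compute_ki_map(
    suv_t1: ImageVolume,
    act_t2: ImageVolume,
    if_: InputFunction,
    times: TimePair,
    mask: np.ndarray | None = None,
    scaled: bool = True,
) -> ImageVolume:
    """Voxelwise two-point Patlak slope.

    ``act_t2`` must arrive co-registered on the exact grid of ``suv_t1``
    (registration is an upstream concern); units of tissue and plasma must be
    consistent at each time point.  With ``scaled=True`` (default) the output
    stores 100*Ki with unit tag ``KI_SCALED``; otherwise raw Ki in 1/min.
    Negative Ki values are preserved — any clamping happens at feature
    discretization time.
    """
    if not suv_t1.same_grid(act_t2):
        raise ValueError("t1 and t2 volumes are not on the same grid (shape/spacing/origin)")
    cp1, cp2 = if_.value(times.t1), if_.value(times.t2)
    if cp1 <= 0 or cp2 <= 0:
        raise ValueError("Cp(t1) and Cp(t2) must be positive")
    denom = patlak_denominator(if_, times)
    if denom <= 0:
        raise ValueError(
            f"non-positive Patlak denominator ({denom:.6g}); "
            "invalid acquisition timing or input-function shape"
        )
    numer = act_t2.data / cp2 - suv_t1.data / cp1
    ki = numer / denom
    if mask is not None:
        ki = np.where(np.asarray(mask, bool), ki, 0.0)
    if scaled:
        return suv_t1.with_data(KI_DISPLAY_SCALE * ki, unit_tag=UnitTag.KI_SCALED)
    return suv_t1.with_data(ki, unit_tag=UnitTag.KI_RAW)
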