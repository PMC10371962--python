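"""Synthetic dual-time-point phantoms and multi-center lesion cohorts.

Two generators make every pipeline stage testable without patient data:

* image level — Patlak-consistent phantom studies.  Every voxel follows
  C(t) = Ki * int_0^t Cp + V * Cp(t) for a known input function, so a
  noiseless study is an algebraic identity for the two-point Ki estimator.
  Lesions are spheres with Gaussian-random-field Ki texture (seeded
  correlation length and amplitude, clipped at zero); an optional blood-pool
  sphere carries the pure plasma signal Cp(t) for input-function scaling.
  Noise is multiplicative Gaussian per voxel per time point
  (coefficient-of-variation parameterized, independent across time points);
  Poisson/reconstruction realism is out of scope.

* table level — feature tables for two centers with planted batch effects
  (per-center additive offset and multiplicative scale) and a planted
  outcome effect (mean shift in pooled-SD units on a named feature subset),
  for harmonization, univariate and modeling tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .input_function import InputFunction
from .volumes import ImageVolume, UnitTag, sphere_mask


def simulate_input_function(
    amplitudes, decay_rates, peak_time_min: float = 1.0
) -> InputFunction:
    """Validated multi-exponential plasma curve (see :class:`InputFunction`)."""
    return InputFunction(
        amplitudes=tuple(amplitudes),
        decay_rates=tuple(decay_rates),
        peak_time_min=peak_time_min,
    )


# ----------------------------------------------------------- image phantoms

@dataclass
class LesionSpec:
    center_mm: tuple[float, float, float]
    radius_mm: float
    mean_ki: float                  # net influx rate, 1/min
    v_dist: float = 0.5             # apparent distribution volume (dimensionless)
    texture_corr_mm: float = 8.0    # Gaussian-field correlation length
    texture_amp: float = 0.0        # SD of the Ki texture, 1/min

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_ki: float = 0.002
    background_v: float = 0.3
    lesions: list[LesionSpec] = field(default_factory=list)
    blood_center_mm: tuple[float, float, float] | None = None
    blood_radius_mm: float = 12.0
    pure_plasma: bool = True
    noise_cov: tuple[float, float] = (0.0, 0.0)  # per time point

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.noise_cov):
            raise ValueError("noise CoV must be non-negative")
        extent = np.asarray(self.shape) * np.asarray(self.spacing_mm)
        for les in self.lesions:
            c = np.asarray(les.center_mm)
            if np.any(c - les.radius_mm < 0) or np.any(c + les.radius_mm > extent):
                raise ValueError(f"lesion at {les.center_mm} exits the grid")
        if self.blood_center_mm is not None:
            c = np.asarray(self.blood_center_mm)
            if np.any(c - self.blood_radius_mm < 0) or np.any(c + self.blood_radius_mm > extent):
                raise ValueError("blood pool exits the grid")


def gaussian_random_field(shape, spacing_mm, corr_mm: float, rng) -> np.ndarray:
    """Seeded stationary Gaussian field with unit variance and the stated
    correlation length (Gaussian-smoothed white noise, renormalized)."""
    white = rng.standard_normal(shape)
    sigma_vox = [max(corr_mm / s, 1e-6) for s in spacing_mm]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _lesion_masks(spec: PhantomSpec):
    masks = []
    for les in spec.lesions:
        masks.append(
            sphere_mask(spec.shape, spec.spacing_mm, (0.0, 0.0, 0.0), les.center_mm, les.radius_mm)
        )
    blood = None
    if spec.blood_center_mm is not None:
        blood = sphere_mask(
            spec.shape, spec.spacing_mm, (0.0, 0.0, 0.0), spec.blood_center_mm, spec.blood_radius_mm
        )
    for i, m in enumerate(masks):
        if blood is not None and (m & blood).any():
            raise ValueError(f"lesion {i} overlaps the blood pool")
        for j in range(i):
            if (m & masks[j]).any():
                raise ValueError(f"lesions {j} and {i} overlap")
    return masks, blood


def build_ki_truth(spec: PhantomSpec, seed: int) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], np.ndarray | None]:
    """(Ki field in 1/min, V field, lesion masks, blood mask)."""
    rng = np.random.default_rng(seed)
    ki = np.full(spec.shape, spec.background_ki, dtype=float)
    v = np.full(spec.shape, spec.background_v, dtype=float)
    masks, blood = _lesion_masks(spec)
    for les, mask in zip(spec.lesions, masks):
        field_ = les.mean_ki + les.texture_amp * gaussian_random_field(
            spec.shape, spec.spacing_mm, les.texture_corr_mm, rng
        )
        ki[mask] = np.clip(field_[mask], 0.0, None)
        v[mask] = les.v_dist
    return ki, v, masks, blood


def simulate_dtp_study(
    spec: PhantomSpec,
    if_: InputFunction,
    t1_min: float,
    t2_min: float,
    seed: int = 0,
) -> dict:
    """Patlak-consistent two-time-point study.

    Returns ``suv_t1``/``act_t2`` volumes (tissue concentration on the SUV
    scale at each time), the ground-truth ``truth_ki`` map (1/min), the
    lesion masks, and the blood-pool center (or None).  At zero noise the
    two-point Patlak estimator recovers ``truth_ki`` to machine precision.
    """
    if not t2_min > t1_min > 0:
        raise ValueError("need t2 > t1 > 0")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD7)))
    ki, v, masks, blood = build_ki_truth(spec, seed)

    volumes = {}
    for name, t, cov, tag in (
        ("suv_t1", t1_min, spec.noise_cov[0], UnitTag.SUV),
        ("act_t2", t2_min, spec.noise_cov[1], UnitTag.ACTIVITY),
    ):
        cp, integ = if_.value(t), if_.integral(t)
        data = ki * integ + v * cp
        if blood is not None and spec.pure_plasma:
            data[blood] = cp
        if cov > 0:
            data = np.clip(data * (1.0 + cov * rng.standard_normal(spec.shape)), 0.0, None)
        volumes[name] = ImageVolume(
            data=data, spacing=spec.spacing_mm, origin=(0.0, 0.0, 0.0), unit_tag=tag
        )
    volumes["truth_ki"] = ImageVolume(
        data=ki, spacing=spec.spacing_mm, origin=(0.0, 0.0, 0.0), unit_tag=UnitTag.KI_RAW
    )
    volumes["masks"] = masks
    volumes["blood_center"] = spec.blood_center_mm
    return volumes


# ------------------------------------------------------------ table cohorts

@dataclass
class CohortSpec:
    """Two-center lesion cohort with planted batch and outcome effects."""

    n_patients_per_center: int = 20
    lesions_per_patient_mean: float = 2.5   # 1 + Poisson(mean - 1) per patient
    prevalence: float = 0.6                 # fraction of responding lesions
    feature_names: tuple[str, ...] = tuple(f"feat_{i:02d}" for i in range(20))
    effect_features: tuple[str, ...] = ()
    effect_size: float = 0.0                # class mean shift, pooled-SD units
    batch_offsets: tuple[float, float] = (0.0, 0.0)   # per-center additive
    batch_scales: tuple[float, float] = (1.0, 1.0)    # per-center multiplicative
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if any(s <= 0 for s in self.batch_scales):
            raise ValueError("batch scales must be positive")
        if self.n_patients_per_center < 5:
            raise ValueError("need >= 5 patients per center for split protocols")
        unknown = set(self.effect_features) - set(self.feature_names)
        if unknown:
            raise ValueError(f"effect features not in feature list: {sorted(unknown)}")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a lesion feature table per the cohort spec.

    Features are unit-variance Gaussians; responding lesions get a mean
    shift of ``effect_size`` (in pooled-SD units) on the effect features;
    then each center's batch transform x -> scale * x + offset is applied.
    Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    lesion_no = 0
    for c_ix, center in enumerate(("center1", "center2")):
        for p in range(spec.n_patients_per_center):
            patient = f"{center}_pat{p:03d}"
            n_lesions = 1 + rng.poisson(max(spec.lesions_per_patient_mean - 1.0, 0.0))
            for _ in range(n_lesions):
                outcome = int(rng.random() < spec.prevalence)
                values = rng.standard_normal(len(spec.feature_names))
                row = {
                    "lesion_id": f"les{lesion_no:04d}",
                    "patient_id": patient,
                    "center_id": center,
                    "outcome": outcome,
                }
                for name, val in zip(spec.feature_names, values):
                    if outcome and name in spec.effect_features:
                        val = val + spec.effect_size
                    row[name] = spec.batch_scales[c_ix] * val + spec.batch_offsets[c_ix]
                rows.append(row)
                lesion_no += 1
    return pd.DataFrame(rows)
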