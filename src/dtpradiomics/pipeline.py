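"""End-to-end chains: phantom study -> Ki map -> VOIs -> feature table.

`process_study` runs the per-study imaging chain (blood-pool scaling of the
population input function, two-point Patlak Ki map, 30%-of-max SUV
segmentation, VOI transfer, 65+65 feature extraction).  `simulate_image_cohort`
wraps it into a two-center synthetic cohort whose class effect is planted in
the image domain (lesion mean Ki shifted on the log scale by a stated number
of between-lesion SDs) and whose batch effect comes from center-dependent
scanner calibration factors and noise levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .features import extract_all
from .input_function import DEFAULT_POPULATION_IF, InputFunction
from .kinetics import TimePair, blood_pool_activity, compute_ki_map, scale_input_function
from .segmentation import threshold_segment, transfer_voi
from .synthetic import LesionSpec, PhantomSpec, simulate_dtp_study
from .volumes import ImageVolume


def process_study(
    suv_t1: ImageVolume,
    act_t2: ImageVolume,
    if_pop: InputFunction,
    cfg: PipelineConfig,
    lv_center_mm,
    la_center_mm,
    lesion_bboxes: list[tuple[tuple[int, int, int], tuple[int, int, int]]],
) -> list[tuple[pd.Series, pd.Series]]:
    """Per-lesion (static, DTP) feature vectors for one dual-time-point study."""
    blood = blood_pool_activity(suv_t1, lv_center_mm, la_center_mm)
    if_pat = scale_input_function(if_pop, blood, cfg.t1_min)
    ki = compute_ki_map(suv_t1, act_t2, if_pat, TimePair(cfg.t1_min, cfg.t2_min))
    out = []
    for bbox in lesion_bboxes:
        voi_suv = threshold_segment(suv_t1, bbox=bbox, fraction=cfg.threshold_fraction)
        voi_ki = transfer_voi(voi_suv, ki)
        out.append(extract_all(suv_t1, ki, voi_suv, voi_ki, cfg))
    return out


# center-dependent acquisition character of the synthetic cohort: a global
# SUV calibration factor, an extra delayed-scan calibration factor (which
# biases the Ki map), and the per-time-point noise CoV
_CENTER_PROFILE = {
    "center1": {"suv_gain": 1.00, "t2_gain": 1.00, "noise": (0.03, 0.03)},
    "center2": {"suv_gain": 1.10, "t2_gain": 1.12, "noise": (0.05, 0.05)},
}

_GRID = (32, 32, 32)
_SPACING = (4.0, 4.0, 4.0)
_LESION_CENTER = (64.0, 64.0, 64.0)
_BLOOD_CENTER = (96.0, 96.0, 96.0)


def _lesion_phantom(mean_ki: float, radius_mm: float, noise, rng_amp: float) -> PhantomSpec:
    return PhantomSpec(
        shape=_GRID,
        spacing_mm=_SPACING,
        background_ki=0.002,
        background_v=0.3,
        lesions=[
            LesionSpec(
                center_mm=_LESION_CENTER,
                radius_mm=radius_mm,
                mean_ki=mean_ki,
                v_dist=0.6,
                texture_corr_mm=8.0,
                texture_amp=rng_amp,
            )
        ],
        blood_center_mm=_BLOOD_CENTER,
        blood_radius_mm=14.0,
        pure_plasma=True,
        noise_cov=noise,
    )


def simulate_image_cohort(
    n_patients_per_center: int = 12,
    effect_size: float = 0.0,
    seed: int = 0,
    cfg: PipelineConfig | None = None,
    if_pop: InputFunction = DEFAULT_POPULATION_IF,
    prevalence: float = 0.6,
    lesions_per_patient_mean: float = 2.2,
) -> pd.DataFrame:
    """Two-center image-domain cohort processed through the full chain.

    Each lesion lives in its own small phantom.  The class effect acts on
    three independent latent lesion traits, each a standard normal shifted
    for responding lesions by ``effect_size`` (avidity: lognormal mean Ki,
    median 0.025 /min, log-SD 0.35), half that (size: lognormal radius,
    median 11 mm) and 0.7 of it (heterogeneity: lognormal relative texture
    amplitude) — treatment-sensitive lesions modeled as less avid, smaller
    and more homogeneous.  ``effect_size = 0`` is an exact null.  Feature
    batch effects arise from the per-center calibration/noise profile, not
    from any direct feature manipulation.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0)))
    rows = []
    lesion_no = 0
    log_mu, log_sd = np.log(0.025), 0.35
    # bbox around the central lesion, clear of the blood pool
    bbox = ((8, 8, 8), (25, 25, 25))
    for center, profile in _CENTER_PROFILE.items():
        for p in range(n_patients_per_center):
            patient = f"{center}_pat{p:03d}"
            n_lesions = 1 + rng.poisson(max(lesions_per_patient_mean - 1.0, 0.0))
            for _ in range(n_lesions):
                outcome = int(rng.random() < prevalence)
                a_ki, a_r, a_h = rng.standard_normal(3)
                if outcome:
                    a_ki -= effect_size
                    a_r -= 0.5 * effect_size
                    a_h -= 0.7 * effect_size
                mean_ki = float(np.exp(log_mu + log_sd * a_ki))
                radius = float(np.clip(np.exp(np.log(11.0) + 0.2 * a_r), 7.0, 15.0))
                amp_rel = float(np.exp(np.log(0.3) + 0.3 * a_h))
                spec = _lesion_phantom(mean_ki, radius, profile["noise"], amp_rel * mean_ki)
                study = simulate_dtp_study(
                    spec, if_pop, cfg.t1_min, cfg.t2_min,
                    seed=int(rng.integers(2**31 - 1)),
                )
                suv = study["suv_t1"].with_data(study["suv_t1"].data * profile["suv_gain"])
                act = study["act_t2"].with_data(
                    study["act_t2"].data * profile["suv_gain"] * profile["t2_gain"]
                )
                static, dtp = process_study(
                    suv, act, if_pop, cfg, _BLOOD_CENTER, _BLOOD_CENTER, [bbox]
                )[0]
                row = {
                    "lesion_id": f"les{lesion_no:04d}",
                    "patient_id": patient,
                    "center_id": center,
                    "outcome": outcome,
                }
                row.update({f"static_{k}": v for k, v in static.items()})
                row.update({f"dtp_{k}": v for k, v in dtp.items()})
                rows.append(row)
                lesion_no += 1
    return pd.DataFrame(rows)
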