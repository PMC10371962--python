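# dtp-radiomics

Radiomics response prediction from **dual-time-point (DTP) FDG-PET Patlak
Ki parametric maps**.

Standard oncologic FDG-PET is a single static snapshot (an SUV image).
When a routine scan at ~60 min post-injection is followed by a delayed
acquisition, the net metabolic influx rate Ki can be computed voxel-wise as
the slope of the Patlak plot between the two time points:

```
        C(t2)/Cp(t2) − C(t1)/Cp(t1)
  Ki = ───────────────────────────────────,     I(t) = ∫₀ᵗ Cp(τ) dτ
        I(t2)/Cp(t2) − I(t1)/Cp(t1)
```

where C is the tissue concentration and Cp a population-shaped plasma input
function scaled to the patient's image-derived blood-pool activity (spheres
in the left ventricle and atrium on the 60-min image).  The package builds
these Ki maps, extracts a 65-feature radiomics panel (GLCM, NGLDM, GLRLM,
GLZLM, shape, histogram, conventional and discretized first-order indices)
from both SUV and Ki volumes, removes multi-center batch effects with
parametric empirical-Bayes **ComBat**, screens features univariately
(Spearman correlation tiers, per-feature ROC, paired DeLong tests,
Benjamini–Hochberg FDR), and evaluates six multivariate models
({harmonized, raw} × {DTP, static, DTP+static}) built from **mRMR**-selected
features and a gradient-boosted classifier under a repeated, patient-grouped
80/20 protocol with bootstrap-scored random hyperparameter search.

It is aimed at PET methodology researchers who want a tested, fully
synthetic-data-verifiable implementation of this analysis chain: a
Patlak-consistent phantom simulator and a two-center cohort generator make
every stage checkable against planted ground truth without patient data.

## Worked example

```python
import numpy as np
import dtpradiomics as dr

if_pop = dr.DEFAULT_POPULATION_IF
spec = dr.PhantomSpec(
    lesions=[dr.LesionSpec(center_mm=(64, 64, 64), radius_mm=12,
                           mean_ki=0.02, texture_amp=0.005)],
    blood_center_mm=(96, 96, 96),
)
study = dr.simulate_dtp_study(spec, if_pop, t1_min=61, t2_min=133, seed=1)

blood = dr.blood_pool_activity(study["suv_t1"], (96, 96, 96), (96, 96, 96))
if_pat = dr.scale_input_function(if_pop, blood, 61)
ki = dr.compute_ki_map(study["suv_t1"], study["act_t2"], if_pat,
                       dr.TimePair(61, 133), scaled=False)
mask = study["masks"][0]
print(f"planted Ki 0.0200 /min; recovered "
      f"{ki.data[mask].mean():.4f} /min, max error "
      f"{np.abs(ki.data[mask] - study['truth_ki'].data[mask]).max():.2e}")
```

prints

```
planted Ki 0.0200 /min; recovered 0.0208 /min, max error 1.39e-17
```

i.e. on noiseless Patlak-consistent data the two-point estimator recovers
the planted influx map to machine precision, voxel by voxel (the lesion
*mean* is 0.0208 rather than 0.0200 simply because the planted Gaussian
texture field does not average to exactly its nominal level over this
mask — and the estimator reproduces that realized field exactly).  The
estimator and the generating model are algebraic inverses, which is the
core correctness guarantee everything downstream builds on.  The scripts in `examples/`
walk through each later stage (feature extraction, harmonization,
univariate screen, model evaluation) the same way.

A thin CLI mirrors the stages:
`dtpr simulate | ki-map | segment | extract | harmonize | univariate |
train-eval` (each with `--help`).

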