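# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data experiments do and do not demonstrate.

## Two-point Patlak Ki

Under irreversible FDG trapping, tissue concentration follows
`C(t) = Ki·I(t) + V·Cp(t)` with `I(t) = ∫₀ᵗ Cp`, plasma curve `Cp`, net
influx rate `Ki` (min⁻¹ on SUV-normalized concentrations) and apparent
distribution volume `V`.  With two static acquisitions at `t1 < t2` the
Patlak-plot slope has the closed form shown in the README.  Properties that
follow directly and are property-tested: the estimator is homogeneous of
degree zero (any common rescaling of tissue and plasma cancels), strictly
increasing in the delayed-scan uptake, and exact on noiseless model data
for *any* valid plasma curve.

**Input function.**  A patient's full plasma curve is unavailable from two
static scans, so a population-shaped curve is scaled to the image-derived
blood-pool activity at `t1` (mean of a 15 mm left-ventricle and a 10 mm
left-atrium sphere, equal weight).  The population shape is a linear rise
to a peak at 1 min followed by a tri-exponential decay; the default
parameters (amplitudes 8/3/1.2 SUV, decay rates 2/0.15/0.01 min⁻¹) are a
plausible FDG-like shape chosen once and kept configurable — the Patlak
algebra is exercised identically by any smooth decreasing `Cp`, so none of
the correctness guarantees depend on them.  Value and running integral are
closed-form (`expm1`-based to avoid cancellation at small decay rates), so
noiseless recovery is limited only by float arithmetic.

**Timing and registration.**  Defaults `t1 = 61`, `t2 = 133` minutes
(typical routine + delayed acquisition times).  The delayed volume must
arrive co-registered on the grid of the first scan; a grid-equality check
guards this, and a non-positive Patlak denominator (pathological timing or
plasma shape) is a hard error rather than a silent NaN.  Negative Ki
voxels are preserved in the raw map; they clamp to the lowest bin at
feature discretization.

## Segmentation

Lesion VOIs are voxels at or above 30% of the regional maximum SUV,
restricted to the 26-connected component containing the maximum voxel.
The maximum is regional (a user bounding box), so multiple lesions per
study segment independently; 26-connectivity is the common PET convention
(the threshold mask is provably monotone in the threshold fraction).  VOI
transfer to the Ki map copies the mask (grids must match) and applies
deterministic voxel edits, additions before removals.

## Feature panel

65 features per lesion per image, computed after resampling volume and
mask to 4 mm isotropic voxels (linear interpolation for intensities,
nearest for masks, physical edges preserved) and absolute-bound
discretization: 64 bins over [0, 20] on the SUV scale, Ki maps first
multiplied by 100 to share that window.  Bin index is
`floor((x − min)/(max − min)·N) + 1` clamped to `[1, N]`; because the
bounds are absolute, adding a constant to an image *changes* the features,
deliberately.

Conventions fixed (and oracle-tested) per family:

- **GLCM** (7): 13 unique 3D directions at distance 1, symmetric,
  aggregated into one matrix before normalization ("merged" aggregation);
  entropy in nats with a base-2 twin.
- **NGLDM** (3): neighborhood gray-tone differences over 26-connected
  within-VOI neighbors; coarseness capped at 10⁶ for flat lesions.  Note
  that under fixed-bin discretization coarseness responds to the *spatial
  scale* of texture, not its amplitude (amplitude spreads occupancy over
  proportionally more gray levels, which cancels); NGLDM contrast is the
  amplitude-sensitive member, and the tests assert exactly that pair of
  monotonicities.
- **GLRLM** (11): VOI-interrupted runs along the 13 directions, one merged
  matrix; run percentage is runs/(voxels·directions) so it stays in (0, 1].
- **GLZLM** (11): zones are 26-connected equal-level components; zone
  percentage is zones/voxels.
- **Shape** (5): voxel-face-counted surface; sphericity
  `π^(1/3)(6V)^(2/3)/S` and compacity `V/(√π·S^(3/2))`.  Face counting
  makes the surface of a digital ball converge to 1.5× the smooth sphere
  (staircase effect), so ball sphericity tends to 2/3 rather than 1 — a
  known, documented bias of this surface definition.
- **Histogram** (4): bin-frequency entropy/uniformity plus AUC-CSH, the
  area under the cumulative intensity–volume histogram (fraction of volume
  ≥ x·max, trapezoid over 1001 points of x ∈ [0, 1]).
- **Conventional / discretized** (12 + 12): first-order indices on the raw
  resampled intensities and on bin-center surrogates.  Quantiles use
  linear interpolation; SD/skewness/kurtosis use population moments with
  the zero-spread case mapped to 0; peak is the mean over a 0.5 mL sphere
  centered on the maximum voxel intersected with the VOI; TLG is
  mean × volume (mL).

Degenerate single-level lesions get deterministic fallbacks (GLCM
correlation 1, energy 1; NGLDM contrast/busyness 0) instead of NaN, so
every extracted vector is finite by construction (fuzz-tested).

## ComBat harmonization

Parametric empirical-Bayes ComBat: per-feature standardization against the
pooled mean/variance (batch-design OLS), per-batch location/scale
estimates shrunk toward a normal / inverse-gamma prior with
method-of-moments hyperparameters, solved by joint fixed-point iteration
to 1e-6 relative tolerance, then the inverse transform.  The
implementation reproduces the Bioconductor reference numerically
(cross-checked in the test suite via Rscript).  Zero-variance features
pass through unchanged with a warning.  EB shrinkage leaves per-feature
residual batch gaps at the sampling-noise scale — harmonization
equalizes batches in distribution, not feature-by-feature exactly — so
recovery is assessed as the across-feature mean standardized gap.

An optional outcome covariate can be protected during fitting.  By
default the modeling protocol fits ComBat on the training split only and
applies it to the test split; fitting on all lesions before the split
(`combat_mode="all"`) is available for comparison but leaks test-set
information into the transform.

## Univariate statistics

Per-feature Spearman correlations between static and DTP features are
tiered at |ρ| < 0.5 (low), < 0.7 (moderate), ≥ 0.7 (high); boundaries
assign upward.  AUC is the Mann–Whitney pair statistic (ties half), its
variance and the covariance of two correlated AUCs come from DeLong
placement values, and all tests are two-sided.  BH FDR is the step-up
`q_(i) = min_{j≥i} p_(j)·m/j`; significance of the four-arm DeLong
comparisons uses q < 0.05 within each 65-feature comparison.  The oriented
AUC `max(AUC, 1−AUC)` is reported only in the per-feature screen; DeLong
comparisons use raw score orientation.

## Multivariate protocol

mRMR uses the greedy mutual-information-difference scheme with 3-state
discretization at μ ± σ; ties break toward the canonical feature order
(with a 1e-9 tolerance so float noise cannot reorder exact ties).  The
combined DTP+static variant selects the top 10 of each set, pools the 20
and re-runs mRMR down to 10.

One evaluation repeat: patient-grouped 80/20 train/test split (lesion-level
behind a flag), optional ComBat fit on the training split, mRMR on the
training split, an inner 80/20 train/validation split, random search over
a compact gradient-boosting grid (depth 2–4, learning rate 0.05–0.3,
30–100 trees, row/column subsampling) where each candidate is scored by
mean validation AUC over B bootstrap resamples of the inner-training
lesions, winner refit on the full training split, metrics on the untouched
test split.  ACC/SEN/SPE use a 0.5 probability threshold with responding
= positive; the CI over repeats is the 2.5/97.5 percentile; variants are
compared metric-wise with two-sided Mann–Whitney (exact for small
tie-free samples, tie-corrected normal otherwise).  The protocol exposes
its per-repeat training artifacts (ComBat digest, selected features, tuned
hyperparameters) so leakage-freedom is testable: corrupting test-row
features must leave them bit-identical.

Defaults are 100 repeats with 1000-scale search effort; the test suite and
the acceptance script run scaled-down settings (20 repeats, 6 candidates,
25 bootstrap resamples; cohorts of ~40 patients / ~90 lesions across two
centers), sizes chosen to keep desk runs short while leaving the Monte
Carlo error of mean AUC near 0.02.

A statistical caveat worth stating explicitly: repeated splits of a single
finite cohort are *dependent*.  Under a null cohort, feature selection
favors the features most accidentally correlated with the labels in the
training rows, and those correlations regress past zero in the
complementary test rows, so the mean test AUC over many splits of one null
cohort sits systematically below 0.5 even though the protocol is
unconditionally calibrated (its expectation over independent cohorts is
exactly 0.5, since test lesions are independent of everything the model
saw).  Calibration claims are therefore evaluated across independent null
cohorts, with the confidence interval taken over cohort-level means; a
SEM over dependent within-cohort repeats would be invalid.

## Synthetic data: what it does and does not show

The phantom generator draws every voxel from the same Patlak model the
estimator inverts, with Gaussian-random-field lesion texture (stated
correlation length and amplitude, clipped at zero), an optional
pure-plasma blood-pool sphere, and multiplicative Gaussian noise per time
point.  The image-domain cohort plants the class effect in three latent
lesion traits (avidity, size, heterogeneity; shifts of s, 0.5s and 0.7s
latent SDs for effect size s) and the batch effect in per-center
calibration gains and noise levels — never directly in features.  The
table-level cohort generator plants Gaussian feature shifts and
affine batch transforms directly for statistics-level tests.

Passing tests therefore demonstrate internal consistency and correct
statistics under the stated generative models.  They do not demonstrate
robustness to what the simulator omits: scanner PSF and reconstruction
artifacts, Poisson counting noise, attenuation/scatter, respiratory
motion, mis-registration between time points, segmentation variability,
or real biological feature correlations.  Absolute performance numbers on
synthetic cohorts are properties of the generator, not clinical claims.

## Known limitations

- Two-point Patlak assumes irreversible trapping and a positive
  denominator; late dephosphorylation (k4 > 0) biases Ki low.
- The population input-function shape is assumed; only its scale is
  patient-specific.
- Texture conventions follow one fixed, tested set of choices; byte parity
  with any particular radiomics program is out of scope.
- Patient-grouped splitting is the default; per-lesion splitting (shared
  patients across splits) is available but optimistic.
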