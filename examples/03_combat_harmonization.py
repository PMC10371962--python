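"""Remove planted two-center batch effects with ComBat.

Generates a 65-feature cohort where center 2 measures every feature with a
+2 SD offset and a x3 scale, then shows the standardized between-center
gap and SD ratio before and after empirical-Bayes harmonization.
"""

import numpy as np

from dtpradiomics.harmonization import combat_harmonize
from dtpradiomics.synthetic import CohortSpec, simulate_cohort
from dtpradiomics.tables import feature_columns

spec = CohortSpec(
    n_patients_per_center=100,
    lesions_per_patient_mean=2.0,
    feature_names=tuple(f"f{i:02d}" for i in range(65)),
    batch_offsets=(0.0, 2.0),
    batch_scales=(1.0, 3.0),
    seed=7,
)
table = simulate_cohort(spec)
harm = combat_harmonize(table)
fc = list(feature_columns(table))


def report(tab, label):
    g = tab.groupby("center_id")[fc]
    means, sds = g.mean(), g.std()
    pooled = np.sqrt((sds.iloc[0] ** 2 + sds.iloc[1] ** 2) / 2)
    gap = (np.abs(means.iloc[0] - means.iloc[1]) / pooled).mean()
    ratio = (sds.iloc[1] / sds.iloc[0]).mean()
    print(f"{label:14s} mean |gap| = {gap:5.3f} SD   mean SD ratio = {ratio:5.3f}")


report(table, "before ComBat")
report(harm, "after ComBat")
print()
print("Harmonization equalizes the centers in distribution; the residual")
print("per-feature gap is at the sampling-noise scale of ~400 lesions.")
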