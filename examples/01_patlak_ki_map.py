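"""Build a dual-time-point phantom study and recover its Ki map.

Simulates a textured lesion plus a pure-plasma blood pool, scales the
population input function to the image-derived blood activity, computes
the two-point Patlak slope and compares it with the planted ground truth.
"""

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
err = np.abs(ki.data[mask] - study["truth_ki"].data[mask]).max()
print(f"blood-pool SUV at t1:        {blood:.4f}")
print(f"planted lesion mean Ki:      0.0200 /min")
print(f"recovered lesion mean Ki:    {ki.data[mask].mean():.4f} /min")
print(f"max voxel recovery error:    {err:.2e} /min")
print("On noiseless Patlak-consistent data the two-point slope inverts the")
print("generating model exactly; the error above is float arithmetic only.")
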