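"""Simulate raw multi-echo FLASH signals and fit quantitative maps.

One phantom subject's brainstem slab is pushed through the full MPM chain:
double-angle B1 mapping, joint multi-contrast R2* estimation (ESTATICS
with one weighted pass), dual-flip-angle R1/amplitude, MT saturation and
proton-density calibration.  Nucleus means from the fitted maps are then
compared with the generating table values.
"""

import numpy as np

from qmripls import mpm, phantom, prep

truth = phantom.make_phantom(phantom.PhantomSpec(n_subjects=5, seed=2))
trains, (s_a, s_2a) = phantom.simulate_flash_signals(truth, 0, noise_sd=0.5)

mask = np.ones(truth.spec.slab_shape, bool)
b1 = mpm.estimate_b1_dam(s_a, s_2a, mpm.DAM_ALPHA_DEG, mask)
maps = mpm.fit_mpm(trains, mask, b1=b1, wm_mask=truth.slab_wm_mask)

print(f"B1 field: max |fitted - true| = {np.abs(b1.f - truth.slab_b1).max():.4f}")
print("nucleus means, fitted vs generating value:")
for name in phantom.NUCLEI:
    roi = prep.threshold_mask(truth.slab_probs[name],
                              prep.ROI_THRESHOLDS[name], name=name)
    for prm, vol in (("R1", maps.r1), ("MTsat", maps.mtsat),
                     ("R2star", maps.r2star), ("PD", maps.pd)):
        fit = prep.extract_roi_mean(vol, roi)
        gen = truth.behavior.loc[0, f"{name}_{prm}"]
        print(f"  {name:4s} {prm:7s} fitted {fit:8.3f}   generating {gen:8.3f}")
    break  # one nucleus is enough to show the idea; drop this to see all
# R2* is exact by construction (log-linear model is the generator); R1 and
# MTsat carry the small bias of the rational steady-state approximation.
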