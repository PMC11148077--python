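"""Forward-simulate multi-shell diffusion signals and dictionary-fit NODDI.

A handful of voxels with known (NDI, ODI, FW) are simulated with the
Watson stick/tensor/ball model on the study's 109-direction scheme, Rician
noise is added at SNR 30, and the AMICO-style NNLS dictionary fit
recovers the parameters.
"""

import numpy as np

from qmripls import noddi

scheme = noddi.default_scheme()
rng = np.random.default_rng(3)
truths = [(0.65, 0.25, 0.05), (0.45, 0.55, 0.15), (0.80, 0.10, 0.00)]

dwi = np.empty((len(truths), 1, 1, scheme.bvals.size))
for i, (ndi, odi, fw) in enumerate(truths):
    params = noddi.NoddiVoxelParams(
        f_iso=fw, f_ic=ndi, kappa=float(noddi.kappa_from_odi(odi)),
        mu=rng.normal(size=3))
    clean = 1000.0 * noddi.predict_signal(params, scheme)
    sigma = 1000.0 / 30.0
    dwi[i, 0, 0] = np.abs(clean + rng.normal(0, sigma, clean.size)
                          + 1j * rng.normal(0, sigma, clean.size))

maps = noddi.fit_volume(dwi, scheme, np.ones((len(truths), 1, 1), bool))
print("true (NDI, ODI, FW)  ->  fitted")
for i, t in enumerate(truths):
    print(f"  {t}  ->  ({maps.ndi[i, 0, 0]:.3f}, "
          f"{maps.odi[i, 0, 0]:.3f}, {maps.fw[i, 0, 0]:.3f})")
# Coherent voxels recover to within a few hundredths at SNR 30.  The
# highly dispersed voxel (ODI 0.55) is the hard case: its signal is nearly
# isotropic, so the noisy per-voxel direction estimate is poor and the fit
# systematically overestimates dispersion — a known property of
# orientation-dispersion estimation at low anisotropy, not specific to the
# dictionary approach.
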