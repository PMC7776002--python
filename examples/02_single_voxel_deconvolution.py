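"""Single-voxel spherical deconvolution with and without correction.

Simulates a noiseless single fiber under a gradient deviation and compares
the primary FOD peak of four estimators against the true fiber direction:
dRL/CSD with the imposed sampling (uni) and with the effective one (mod).
"""

import numpy as np

from gnlsd import (
    CoilTensor,
    FiberConfig,
    csd_deconvolve,
    csd_mod_deconvolve,
    make_scheme,
    tensor_signal,
)
from gnlsd.csd import response_to_zonal
from gnlsd.drl import ResponseModel, drl_fit
from gnlsd.peaks import angular_deviation, constraint_mesh, extract_peaks, fit_sh_to_fod

truth = np.array([1.0, 1.0, 0.2])
truth /= np.linalg.norm(truth)
coil = CoilTensor.from_deviation(np.array([-0.13, -0.14, -0.05]))
scheme = make_scheme(3000.0, 60)
response = ResponseModel()  # eigenvalues [1.7, 0.2, 0.2]e-3 mm2/s
dict300 = constraint_mesh()

# the voxel experiences the effective b-matrices
signal = tensor_signal(FiberConfig(truth[None, :]), scheme.effective(coil).bmatrices)
S_dw = signal[scheme.dwi_mask]
dirs_dw = scheme.directions[scheme.dwi_mask]

peaks = {}
f = drl_fit(signal, scheme, response, dict300)                 # dRL-uni
peaks["dRL-uni"] = extract_peaks(fit_sh_to_fod(f)).directions[0]
f = drl_fit(signal, scheme, response, dict300, coil=coil)      # dRL-mod
peaks["dRL-mod"] = extract_peaks(fit_sh_to_fod(f)).directions[0]
c = csd_deconvolve(S_dw, dirs_dw, response_to_zonal(response, 3000.0))
peaks["CSD-uni"] = extract_peaks(c).directions[0]
c = csd_mod_deconvolve(S_dw, scheme, coil, response)
peaks["CSD-mod"] = extract_peaks(c).directions[0]

print("noiseless angular deviation of the primary FOD peak from truth:")
for name, p in peaks.items():
    print(f"  {name}: {angular_deviation(p, truth):6.3f} deg")
print("\nThe uniform fits carry the orientation bias induced by the coil")
print("deviation; rebuilding the dRL H-matrix from the effective b-matrix")
print("removes it, and the CSD semi-correction removes most of it.")
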