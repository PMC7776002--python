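"""Whole-volume phantom: spatial structure of the angular bias.

Builds a parametric phantom whose coil-tensor deviation grows quadratically
from the isocenter (identity) to the volume corners, fits every voxel with
dRL using the imposed (uni) and the local effective (mod) b-matrices, and
relates the per-voxel angular deviation to the local coil-deviation
magnitude ||dL||_F.
"""

import numpy as np

from gnlsd import PhantomSpec, make_scheme, run_phantom_study

scheme = make_scheme(3000.0, 60)
spec = PhantomSpec(shape=(13, 13, 7), snr=None)  # noiseless
res = run_phantom_study(spec, scheme, seed=0)

for method in ("drl-uni", "drl-mod"):
    dev = res.deviation_maps[method]
    print(f"{method}: median {np.median(dev):.3f} deg, max {dev.max():.3f} deg, "
          f"Spearman(||dL||_F, deviation) = {res.correlations[method]:+.2f}")

print("\nThe uniform fit is unbiased at the isocenter and increasingly")
print("wrong toward the periphery, tracking the coil-deviation magnitude;")
print("the voxel-wise corrected fit stays below a tenth of a degree")
print("everywhere.  With snr=30.0 instead of None the same structure")
print("appears on top of the noise floor.")
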