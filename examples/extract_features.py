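"""Extract the thirteen magnitude and phase features for one phantom.

Runs VOI segmentation, R2* relaxometry, 3D phase unwrapping, the band-passed
short-range perturbation (s) map and the perturbation-propagation (p) map,
then prints the per-inlay medians of the key channels (standardized units).
"""

import numpy as np

from spiolocate import RunConfig
from spiolocate.pipeline import extract_features, simulate_phantom

cfg = RunConfig(seed=42)
spec, truth, baseline, contrast = simulate_phantom(cfg)
bundle = extract_features(contrast, baseline, cfg)  # pre-aligned pair

stack = bundle.stack
print(f"channels: {', '.join(stack.names)}")
print(f"VOI: {bundle.voi.count()} voxels; noise floor {bundle.noise_floor:.1f}")
from scipy import ndimage

print(f"{'uM':>5} {'rho_e1':>8} {'drho_e3':>8} {'r2star':>8} {'|s|shell':>9} {'p shell':>8}")
struct = np.ones((3, 3, 3), dtype=bool)
for i, inlay in enumerate(spec.inlays, start=1):
    sel = truth.inlay_labels == i
    shell = ndimage.binary_dilation(sel, struct, 2) & ~sel & bundle.voi.data
    row = [float(np.median(stack.channels[ch].data[sel]))
           for ch in ("rho_e1", "drho_e3", "r2star")]
    row += [float(np.median(np.abs(stack.channels["s"].data[shell]))),
            float(np.median(stack.channels["p"].data[shell]))]
    print(f"{inlay.iron_concentration:>5.0f} " + " ".join(f"{v:8.2f}" for v in row))
bg = bundle.voi.data & (truth.inlay_labels == 0)
row = [float(np.median(stack.channels[ch].data[bg])) for ch in ("rho_e1", "drho_e3", "r2star")]
row += [float(np.median(np.abs(stack.channels["s"].data[bg]))),
        float(np.median(stack.channels["p"].data[bg]))]
print(f"{'bg':>5} " + " ".join(f"{v:8.2f}" for v in row))

# Higher iron concentration shows up as darker signal (negative rho), larger
# change versus baseline (drho), and faster relaxation (r2star) inside the
# compartment; the dipole field of a z-aligned cylinder is largest just
# OUTSIDE it, so the short-range perturbation (s) and its growth rate (p)
# are read off a 2-voxel shell around each inlay.  Background medians sit
# near 0 by construction (robust standardization over the VOI).
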