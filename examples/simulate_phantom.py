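"""Simulate the agarose block phantom and inspect its signal physics.

Builds the default five-inlay dilution-series phantom (480 down to 30
labeled cells per mm^3), synthesizes the baseline/contrast multi-echo
dataset pair, and prints the per-inlay magnitude decay across echoes.
"""

import numpy as np

from spiolocate import RunConfig
from spiolocate.pipeline import simulate_phantom

cfg = RunConfig(seed=42)
spec, truth, baseline, contrast = simulate_phantom(cfg)

print(f"grid {contrast.shape}, voxel {cfg.protocol.voxel_size} mm, "
      f"TE {cfg.protocol.echo_times} ms")
print(f"{'inlay':>6} {'cells/mm^3':>11} {'uM Fe2O3':>9} "
      + " ".join(f"|S(TE{e+1})|" for e in range(3)))
for i, inlay in enumerate(spec.inlays, start=1):
    sel = truth.inlay_labels == i
    mags = [float(v.data[sel].mean()) for v in contrast.magnitude]
    print(f"{i:>6} {inlay.cell_density:>11.0f} {inlay.iron_concentration:>9.0f} "
          + " ".join(f"{m:8.1f}" for m in mags))
bg = (truth.inlay_labels == 0) & (baseline.magnitude[0].data > 50)
print("background magnitude at TE1:", round(float(contrast.magnitude[0].data[bg].mean()), 1))

# The mean magnitude decays faster in the higher-concentration compartments:
# that accelerated decay (R2* = background + relaxivity * concentration) is
# the quantitative handle the pipeline uses to recover iron concentration.
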