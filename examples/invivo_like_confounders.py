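"""Localization in the presence of low-proton-density confounders.

The in-vivo-like phantom adds textured background and air/bone-analog
regions that mimic iron in the magnitude data (dark, elevated apparent R2*)
but carry no susceptibility source, so they lack the short-range phase
signature.  Runs the full pipeline and reports how the classifier treats
the confounders versus the two labeled-cell injections.
"""

import numpy as np

from spiolocate import RunConfig
from spiolocate.pipeline import run_full_pipeline, simulate_phantom

cfg = RunConfig(seed=6)
cfg.phantom.kind = "invivo-like"
run = run_full_pipeline(cfg)

spec, _, _, _ = simulate_phantom(cfg)  # deterministic: same seed, same spec
shape = run.result.positives.shape
X, Y, Z = np.meshgrid(*[np.arange(n) * 0.4 for n in shape], indexing="ij")
conf = np.zeros(shape, dtype=bool)
for reg in spec.low_density_regions:
    d2 = (X - reg.center[0]) ** 2 + (Y - reg.center[1]) ** 2 + (Z - reg.center[2]) ** 2
    conf |= d2 <= reg.radius**2

pos = run.result.positives.data
print(run.report.to_dataframe().round(3).to_string(index=False))
print(f"\nfalse-positive rate inside the {int(conf.sum())} confounder voxels: "
      f"{pos[conf & ~run.truth.positive_mask.data].mean():.3f}")
print(f"overall specificity across the VOI: {run.report.global_specificity:.3f}")

# Despite looking iron-like in magnitude alone, the signal-void confounders
# are (almost) never classified as containing labeled cells - the combined
# magnitude + phase feature space separates them.
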