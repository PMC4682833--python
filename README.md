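# spiolocate

Localization and quantification of SPIO-labeled cells from multi-echo
gradient-echo MRI.

Cells labeled with superparamagnetic iron oxide (SPIO) nanoparticles act as
a strong local dephasing source: magnitude signal decays faster
(R2\* = 1/T2\* rises roughly linearly with iron oxide concentration) and the
surrounding phase acquires a dipole-shaped perturbation that grows with echo
time. Either effect alone is ambiguous — air, bone and other low
proton-density structures also look dark with elevated apparent R2\*. This
package implements a multiparametric approach: it extracts thirteen
magnitude- and phase-derived features per voxel from a pair of multi-echo 3D
FLASH scans (a pre-injection *baseline* and a *contrast* scan), classifies
every voxel as *containing* / *not containing* labeled cells with an
RBF-kernel C-support-vector classifier, and converts R2\* inside positive
voxels into iron oxide concentration (μM Fe₂O₃) through a linear calibration
R2\* = R2\*₀ + r·c.

The feature set per voxel: per-echo signal intensity ρ, per-echo change
versus the registered baseline Δρ = |ρ − ρ_baseline|, the R2\* rate from a
weighted log-linear fit of ρ(TE), per-echo baseline-subtracted unwrapped
phase φ, an unreliable-phase indicator (TE→0 extrapolation screening), the
band-passed short-range phase perturbation map *s*, and the perturbation
propagation rate *p* = d|s|/dTE. Baseline-to-contrast alignment uses rigid
normalized-mutual-information registration (optional demons-style non-rigid
refinement), applied to phase through the complex representation.

Because real scanner data cannot ship with the package, a physics-based
simulator stands in for the scanner: agarose block phantoms with cylindrical
inlays holding a 2:1 dilution series of labeled cells (480 down to 30
cells/mm³ ≙ 313 down to 19 μM Fe₂O₃), imaged at TE = {2.54, 3.78, 11.34} ms,
TR = 200 ms, flip 25°, 0.4 mm isotropic voxels, 4.7 T. The forward model is
mono-exponential T2\* decay plus dipole-kernel convolution phase plus
complex Gaussian noise (Rician magnitude), with full ground truth. An
in-vivo-like variant adds textured background and signal-void confounders.

## Worked example

```python
from spiolocate import RunConfig
from spiolocate.pipeline import run_transfer_experiment

run_train, run_eval = run_transfer_experiment(RunConfig(seed=7), RunConfig(seed=8))
print(run_eval.report.to_dataframe().round(3).to_string(index=False))
```

prints (evaluation phantom, pre-trained model, ~2 min per phantom):

```
 region  c_real_uM  sensitivity  specificity  vol_detected/vol_real  c_detected_uM  c_detected_std_uM
      1      313.0        0.973        0.996                  0.978        323.521         178.125
      2      156.0        1.000        0.993                  1.009        151.252          65.916
      3       78.0        1.000        0.991                  1.011         82.601          21.092
      4       38.0        1.000        0.987                  1.016         39.894          13.612
      5       19.0        0.944        0.983                  0.970         20.501          10.774
```

Each row is one inlay of the dilution series: `sensitivity` /
`specificity` are voxel classification rates inside the inlay plus a
3-voxel background shell, `vol_detected/vol_real` the detected-to-true
volume ratio (positives attributed to the nearest inlay within 3 voxels),
and `c_detected` the mean ± std concentration recovered from R2\* over the
detected voxels. Sensitivity falls and the concentration spread grows
toward the 19 μM inlay (≈2 labeled cells per 0.4 mm voxel), the detection
limit; the 313 μM inlay loses its longest echo to the noise floor, which
widens its concentration spread.

The `examples/` scripts walk through the individual capabilities
(simulation, feature extraction, the transfer experiment, the in-vivo-like
confounder phantom). A thin CLI mirrors the pipeline:
`spiolocate simulate|run|transfer|evaluate --help`.

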