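# Methods

## Forward model (the simulator)

Each voxel of a multi-echo 3D FLASH acquisition is modeled as

    S(TE) = PD · exp(−(R2*₀ + r·c)·TE) · exp(i·(φ₀ + 2π·Δf·TE + φ_dip(TE))) + ε

with proton density `PD` (arbitrary units; ~100 inside 2% agarose, 0 in
air), background relaxation rate `R2*₀` (default 25 s⁻¹), relaxivity `r`
(s⁻¹ per μM Fe₂O₃), local iron oxide concentration `c` (μM), a smooth
background off-resonance field `Δf` (low-order polynomial, seeded
coefficients up to ±150 Hz linear and ±50 Hz quadratic — enough to wrap the
longest echo a few times), an RF phase offset `φ₀`, and complex Gaussian
noise `ε` that makes the stored magnitude Rician. The susceptibility phase
`φ_dip` is the concentration map scaled to a dimensionless susceptibility
(default 3·10⁻³ ppm/μM), convolved with the unit dipole kernel
(Fourier-domain `1/3 − k_z²/|k|²`, k = 0 zeroed, k_z along B0), times
γ·B0·TE; it is exactly linear in both concentration and TE. Flip-angle/TR
dependence, k-space artifacts, motion and particle degradation are out of
scope.

The default *block phantom* renders five cylindrical labeled-cell
compartments (axis along z) in a 2:1 dilution series, 480 → 30 cells/mm³,
mapped to 313 → 19 μM Fe₂O₃ by the fabrication lookup table
{(30,19), (60,38), (120,78), (240,156), (480,313)} with linear
interpolation; an analytic mode (90 pg/cell ÷ M(Fe₂O₃)) is provided but
deliberately not the default since it gives ≈16.9 μM at 30 cells/mm³, not
the fabricated 19 μM. Compartment voxels are assigned by ≥50% cylinder
occupancy on a 3³ sub-grid; the proton-density block boundary is rendered
with per-axis partial-volume fractions so sub-voxel phantom positions are
faithful (important for registration tests). Compartments keep ≥1.2 mm of
agarose between themselves and every block face, as embedded compartments
do.

### Default study conditions and their calibration

Protocol: TE {2.54, 3.78, 11.34} ms, TR 200 ms, flip 25°, 4.7 T, 0.4 mm
isotropic voxels. The printed resolution of such protocols is sometimes
given in cm; the per-voxel arithmetic (30 cells/mm³ ≈ 2 cells per voxel)
fixes 0.4 mm. The default grid is 48×128×28 with compartments of radius
3.6 mm and height 5.6 mm — a desk-scale rendering of the Ø10 mm × 8 mm
fabricated geometry chosen so a full transfer experiment runs in minutes on
one CPU; the geometry is configurable.

Noise defaults to complex σ = 5% of the noiseless background magnitude at
the first echo (SNR ≈ 20). The relaxivity default r = 1.0 s⁻¹/μM was
calibrated against three anchors of the phantom-study regime rather than
invented: (i) per-voxel detected-concentration spreads of ±8–14 μM at the
low inlays imply σ(R2\*) ≈ 8–10 s⁻¹ at this noise level, i.e. r ≈ 1;
(ii) at r = 1 the 313 μM compartment's TE = 11.34 ms signal falls below the
noise floor, reproducing the known long-TE underestimation mechanism at the
highest concentration; (iii) the training phantom then detects the 19 μM
compartment almost completely while an independent evaluation phantom
detects it only partially — the expected difficulty ordering. The
susceptibility scale (3·10⁻³ ppm/μM) puts the strongest compartment's
dipole phase at ~1–2 rad at the second echo and the weakest near the phase
noise floor.

The *in-vivo-like* variant adds ±15% smooth proton-density/R2\* texture,
two labeled-cell inlays in opposite half-spaces, and ≥2 spherical
low-proton-density regions (PD multiplier ≤ 0.1, elevated R2\*, zero
susceptibility) that mimic iron in magnitude but not in phase — the
discriminative premise of the multiparametric approach.

## Feature extraction

**VOI.** Two-class fuzzy c-means (m = 2) on an (intensity,
3³-neighborhood-mean) feature pair of the first-echo magnitude, membership
threshold 0.5, largest connected component, morphological closing, hole
filling. The closing seals pinholes so interior signal voids (strong SPIO
compartments) remain enclosed holes and are retained.

**R2\*.** Per voxel, weighted least squares on log-magnitude with
squared-magnitude weights (the first-order correct weighting for
log-transformed data at moderate SNR). Echoes at or below the noise floor
(default 2× the median air magnitude) are excluded; voxels left with fewer
than two echoes fall back to the two-echo estimate from the shortest pair;
those voxels, and clamped negative rates, are flagged low-confidence.
Nonlinear fitting was rejected: with three echoes it is ill-conditioned and
buys nothing.

**Calibration.** A line through (concentration, median regional R2\*)
pairs of the phantom compartments plus the background point (0, median
background R2\* inside the VOI); medians resist edge partial volume.
Concentration is then `max(0, (R2* − intercept)/slope)`.

**Phase unwrapping.** Best-pair-first region merging: every masked voxel
starts as a region, voxel-face boundaries are scored by mean boundary
magnitude and processed best-first; joining two regions applies the 2π
multiple that minimizes the discontinuity across that boundary (Kruskal-style
merging via union-find with potentials; ties break by the stable edge
order). The output is congruent to the input modulo 2π voxelwise. Each
echo's global 2π gauge is then fixed by bringing the masked median into
(−π, π], so echoes and datasets share one absolute-phase reference — without
this, TE extrapolation and baseline subtraction see arbitrary 2π jumps.
Fields whose true inter-voxel gradient exceeds π (immediately at strong
compartment surfaces) are aliased and cannot be recovered by any unwrapper;
the affected voxels are small in number and their features remain
informative.

**Reliability screening.** Phase is fit linearly against TE per voxel and
extrapolated to the excitation pulse. Unreliable when the RMS residual
exceeds 0.15 rad or the intercept deviates by more than 0.3 rad from a
5-voxel masked-mean-smoothed intercept field. These tolerances were chosen
by Monte-Carlo design so a noise-dominated voxel (i.i.d. uniform phase) is
flagged with probability > 0.99 while a voxel with 0.05 rad phase noise is
essentially never flagged.

**s and p maps.** A radial raised-cosine band-pass (pass periods 2–10
voxels, one-octave low shoulder; no upper shoulder when the short edge sits
at Nyquist, which keeps the filter idempotent) applied to the unwrapped
phase of the second echo, after nearest-neighbor inward filling outside the
VOI and reflect padding (no FFT wrap-around leakage). The p-map band-passes
the baseline-subtracted phase of every echo and fits |s|(TE) per voxel by a
line through the origin (the perturbation vanishes at TE = 0); its slope
(rad/ms) grows with source susceptibility. Source localization thresholds
|s|, takes 26-connected components, merges components whose padded bounding
boxes overlap (the two dipole lobes of one source) and reports
|s|-weighted centroids.

## Registration

Baseline is always the moving image, so the contrast data are never
interpolated. Rigid alignment maximizes Studholme NMI
((H(A)+H(B))/H(A,B), 32-bin joint histogram of trilinearly interpolated
intensities, out-of-field voxels excluded from the histogram) with a
Powell direction-set search over 6 parameters across a ÷4/÷2/÷1 resolution
pyramid; recovery accuracy on simulated data is ~0.1 voxel / 0.2°. Joint
histograms use interpolated intensities rather than partial-volume weight
distribution — simpler, and accurate enough for the recovery tolerances
above. An optional demons-style diffusion-regularized refinement (per-
iteration step cap 0.4 voxel, Gaussian field smoothing, positive Jacobian)
is off by default for phantoms, which are rigidly related. Transforms are
applied to phase data via the complex representation (interpolate re/im,
re-extract magnitude and wrapped phase), never by interpolating wrapped
phase directly.

## Classification

The thirteen channels are standardized by median/MAD over the VOI; the
scalers travel with the trained model so it transfers to independently
acquired scans, whose channels are re-standardized with the *training*
scalers. Per-echo baseline-subtracted phase channels first have their VOI
median removed (residual 2π gauge between independent unwraps). Voxels
flagged unreliable keep an indicator channel and have their phase channels
imputed to the standardized center, so every VOI voxel is classified.

Training samples 15% of VOI voxels uniformly at random (stratified option
available), labeled from the known compartment geometry. A C-SVC with RBF
kernel `exp(−γ‖xᵢ−xⱼ‖²)` and class-weighted penalties (inverse class
frequency) is tuned by stratified five-fold cross-validation over
C ∈ {2⁻³…2⁹}, γ ∈ {2⁻⁹…2³} (powers of 4); ties break toward the smallest
γ, then the smallest C (the smoother boundary). When the training sample
exceeds 2,500 voxels the grid search runs on a seeded stratified subsample
of that size and the selected point is refit on the full sample — the CV
surface is flat enough that the subsample reliably identifies the optimum,
and the search stays proportionate to the rest of the pipeline. The solver
is scikit-learn's SVC; the kernel definition is also exposed directly and
cross-checked against the solver's Gram matrix in the tests.

## Evaluation

Per compartment: sensitivity = TP/real positives and specificity = TN/real
negatives inside an evaluation region of the compartment plus a 3-voxel
background shell (the per-compartment negative-region convention is ours;
global specificity over the whole VOI is reported too). Volume ratios
attribute predicted positives to the nearest compartment within 3 voxels.
Detected concentration statistics run over attributed positives; a
compartment with none is reported missing, not zero. The halo analysis
reports the fraction of false positives within a given dilation shell of
the true positive set.

## What the simulation does and does not show

Passing tests demonstrate that the algorithmic chain — unwrapping,
relaxometry, registration, feature assembly, classifier transfer,
quantification — is correct and self-consistent under the stated forward
model, and that the detection-difficulty ordering of the dilution series
emerges from the physics. They do not certify performance on real scans:
the simulator omits intra-voxel dephasing outside compartments, B1/flip
inhomogeneity, gradient nonlinearity near coil edges, k-space artifacts and
real non-rigid motion. One concrete consequence: in real phantom data false
positives form a tight halo around the compartments (driven by boundary
partial volume and imperfect physical registration), whereas under this
forward model residual false positives are few (~0.5–1%) and spatially
unstructured, so the halo-dominance observation is not reproduced — the
halo analysis is provided, but its real-data behavior should not be
inferred from simulation.

## Numerical choices and degenerate inputs

Phase is stored in [−π, π); integer-scaled phase on disk is rescaled
assuming power-of-two full-scale ranges. Constant images are rejected by
VOI segmentation and NMI (zero entropy). Calibration requires ≥2 distinct
nonzero concentrations. An empty unwrap mask, inverted band edges, single-
class training sets and mismatched grids raise validation errors naming the
offense. Every stochastic step (noise draws, training subsampling, CV
folds) is seeded from one run seed; a full pipeline rerun is bit-identical.

Default problem sizes (48×128×28 grid, ~97k VOI voxels, ~14.6k training
voxels, 49-point CV grid on a 2,500-voxel subsample) were chosen so a
complete train-on-A/evaluate-on-B experiment takes a few minutes on a
single CPU; all of them are configuration values.
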