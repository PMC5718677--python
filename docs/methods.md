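# Methods

This note records the model, the simulator it is calibrated against, the
numerical choices, and what the tests do and do not demonstrate.

## Threshold model

The optimal percent-of-maximum threshold `TS` for delineating one axial
cross-section is modelled linearly in the cross-sectional area `A` (mm²),
the contrast term `1 − 1/TB` (equivalently, up to an exact intercept
shift, `1/TB`), and — in the pooled variants — the post-reconstruction
Gaussian smoothing FWHM (mm). Two regimes are fitted, split at
`A = 133 mm²` (a 13 mm sphere): below it, partial volume makes `TS`
depend steeply on area; above it, area drops out and contrast dominates.
Models are stored canonically as coefficients over
`{intercept, area, inv_tb, fwhm}`; fits using the contrast
parameterization convert exactly (intercept += B_contrast; the 1/TB
coefficient is −B_contrast). Each model carries its calibration ranges;
predictions outside them succeed but set an extrapolation flag, because a
linear calibration has no standing outside the conditions that produced
it.

Standardized coefficients are `β_i = B_i · sd(x_i)/sd(y)`; goodness of
fit is the adjusted `R² = 1 − (1−R²)(n−1)/(n−p−1)`. Reliability is the
cross-validation shrinkage `R² − R²*`, with `R²*` the squared correlation
of observed and predicted thresholds on a held-out validation sample;
shrinkage below 0.10 is taken as the conventional reliability bound. Note
that a correlation-based `R²*` is insensitive to calibration bias — a
model can shrink little and still be biased where validation and
deployment populations differ.

## Phantom simulator

The generator emulates a modified IEC body phantom: six fillable spheres
(10, 13, 17, 22, 28, 37 mm internal diameter; an optional micro-sphere
set of 4.1–8.1 mm) on a 45 mm ring in a 5.4 kBq/ml background, voxel grid
96×96×48 at 2.6×2.6×2 mm. Rendering is analytic: voxels classified
interior/exterior by center distance with a half-diagonal margin carry
exact activities; only surface-straddling voxels are estimated by `N³`
subvoxel supersampling (default `N = 8`; doubling `N` moves the total
integral by < 0.05%).

Reconstruction is emulated as a Gaussian blur plus additive noise:

* **In-plane** FWHM = √(4.6² + s²) mm, combining the transverse system
  PSF with the post-filter width `s` ∈ {4, 6, 8} mm.
* **Axial** FWHM = 5.1 mm, the axial system PSF alone. The post-filter is
  treated as transaxial. This is a deliberate design choice: the method
  lives on slice-to-slice contrast gradients (a small node's slice TB can
  fall from ~13 to ~2 over a few millimetres), and such gradients are
  incompatible with a ~9.5 mm axial kernel. A fully 3D kernel also
  creates an axial spill-in pedestal on edge slices that the linear model
  family cannot express, degrading both the fit and slice-specific
  delineation; the transaxial treatment avoids it.
* **Noise**: zero-mean Gaussian, sd = `noise_sd_fraction` × background
  activity, applied after the blur (post-filtered reconstruction noise is
  approximately Gaussian), then clamped at zero. The default fraction is
  0.05 — a free choice, set once, representative of a well-filtered
  clinical reconstruction; nothing in the calibration depends strongly on
  it below ~0.1. The EM-equivalent iteration count is metadata; an
  optional `noise_iteration_slope` scales the noise sd with iterations
  (default 0 — iteration count is deliberately representable as a null
  effect).

What the simulator does **not** model: sinogram statistics and OSEM
convergence artifacts, attenuation/scatter (threshold calibrations are
known to be insensitive to them), respiratory motion, uptake
heterogeneity, and the flat-topped profiles real reconstructions can show
near the maximum. Passing tests therefore demonstrate internal
consistency of calibration → model → segmentation under Gaussian blur
physics, not clinical accuracy.

## Calibration numerics

* **Area measurement** (default `subvoxel` mode): the supra-level region
  is the 4-connected component containing the ROI maximum
  (4-connectivity prevents diagonal leakage between neighboring hot
  objects); its area comes from marching-squares contours of the
  bilinearly interpolated slice, holes subtracted by shoelace area. This
  matters because the 10 mm² tolerance is ~1.5 in-plane voxels — integer
  voxel counting (retained as `voxel-count` mode) quantizes too coarsely.
  On an analytic Gaussian blob the measured iso-area is within 2% of the
  closed form for contours down to ~30 mm².
* **Threshold search**: all candidates on the 1% grid are evaluated
  (deterministic, direction-free); admissible candidates have
  |area − A| strictly below 10 mm²; the absolute-error minimizer wins and
  exact ties resolve to the center of the largest contiguous plateau —
  robust to the quantization plateaus of near-binary slices. When no
  candidate is admissible the failure carries the best achievable error.
* **TB measurement**: single hottest voxel in the encircling target ROI
  over the mean of the background-ROI union; voxel membership is by
  center inclusion. The background pattern is placed deterministically:
  12 non-overlapping 37 mm ROIs swept along the ring 15 mm + ROI radius
  inside the in-plane edge, rejecting positions whose boundary comes
  within 15 mm of a sphere surface, replicated at ±10 and ±20 mm
  (60 ROIs); smaller background ROIs are concentric with the 37 mm set.
* **Calibration roles**: default is the protocol's central-slice training
  (largest cross-section) plus optional edge-slice validation of the
  spheres larger than the split. For end-to-end self-calibration the
  `edge_training` mode instead records every slice with true area
  ≥ 15 mm² as training: it samples the small-area regime across its full
  extent and matches the slice population segmentation will encounter —
  with central slices only, a 13–37 mm sphere set puts a single area
  level below the split and the area coefficient is unidentifiable.

## Segmentation numerics

Per slice, TB is measured once and the threshold/area interdependence is
resolved by fixed-point iteration on the 1% grid (finite states, so a
fixed point or cycle is reached within 100 steps; cycles resolve to the
visited threshold minimizing |TS − prediction(area(TS))|). The iteration
starts **high**, from the small-area model's area-free prediction: small
cross-sections then settle at the small-model fixed point instead of
being captured by the larger, lower-threshold contour of their blurred
halo, while genuinely large cross-sections fall through to the
large-model fixed point. One guard: a converged contour below 20 mm²
(~3 in-plane voxels, i.e. sub-resolution) indicates degenerate capture
near the top of a very low-contrast profile, and the slice is re-resolved
from the large-model initialization. Failed slices contribute zero area
and are flagged; the volume is `Σ area × slice thickness`, over a slice
range chosen by the user (in phantom experiments, the slices a
co-registered CT would assign to the object).

The boundary `A = 133 mm²` belongs to the small-area model. Predictions
are clipped to [1, 100] with a flag.

## Experiment scales

The packaged experiments (also driven by `scripts/acceptance.py` and the
acceptance tests) use: parameter recovery on 300-record grids
(A ∈ [13, 133] mm², TB log-spaced in [1.5, 70], FWHM ∈ {4, 6, 8}, noise
sd √31.5 and √7.4 for the small/large models — the reported residual mean
squares); ANCOVA power on balanced 3×3 designs with 36 records per cell,
100 replicates; volume recovery on 13–37 mm spheres at prepared contrasts
{4, 8, 16} with one acquisition each; shrinkage on six contrast levels
with ±4/±8 mm edge-slice validation. These sizes keep any single
experiment under a minute on one CPU while leaving the statistical checks
well-powered.

## Known limitations

* Very small, very faint cross-sections (≲ 50 mm² at slice TB ≲ 2.5) are
  intrinsically ill-posed for percent-of-maximum contouring: near the
  top of a blurred profile the area–threshold curve and the model line
  run nearly parallel, so the self-consistent threshold is poorly
  determined. The 13 mm sphere's volume is accordingly unreliable
  (tens of percent error); accuracy within 10% holds from 17 mm up.
* The published coefficient sets are scanner- and protocol-specific;
  applying them to images from a different (simulated or real) system is
  an extrapolation and behaves like one.
* Patient-mode background ROIs are user-supplied; the package does not
  decide what "background" means anatomically.
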