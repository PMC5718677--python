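# petthresh

Slice-specific adaptive-threshold delineation of PET targets, with a
digital sphere-phantom calibration pipeline.

## The problem

Radiotherapy planning on FDG-PET needs a reproducible rule for turning a
blurred, noisy uptake image into a target contour. The workhorse rule is
percent-of-maximum thresholding: keep everything above `TS%` of the
hottest voxel. But the correct `TS` is not a constant — it rises steeply
for small cross-sections (partial-volume effect), falls with
target-to-background contrast, and shifts with the amount of
post-reconstruction smoothing. `petthresh` implements the full adaptive
calibration and application of such thresholds for medical physicists who
want to characterize or deploy the method without (or before) phantom
bench time.

## The method

**Calibration.** Spheres of known internal diameter (4.1–37 mm) in a warm
background are imaged; for each sphere cross-section of known area `A`,
the optimal threshold is found by scanning `TS` in 1% steps until the
auto-contoured area matches `A` to better than 10 mm². Contrast is
measured as `TB` = (max voxel in an ROI encircling the target) / (mean of
a NEMA-style 60-ROI background pattern).

**Models.** The records are fitted by ordinary least squares, split at
`A = 133 mm²` (a 13 mm sphere — the scale where partial-volume effects
take over):

    A ≤ 133 mm²:  TS(%) = B0 + B1·A + B2·(1 − 1/TB)
    A > 133 mm²:  TS(%) = B0 + B1·(1 − 1/TB)

Pooling over reconstruction iteration numbers (which ANCOVA shows do not
move `TS`) and adding the smoothing kernel FWHM as a predictor gives the
deployable pooled models; the published reference coefficients are built
in (`published_models()`):

    TS(%) = 55.94 − 0.25·A + 56.96·(1/TB) + 2.82·FWHM    (A ≤ 133 mm²)
    TS(%) = 33.13 + 60.27·(1/TB) + 0.60·FWHM             (A > 133 mm²)

Model reliability is assessed by cross-validation shrinkage
`R² − R²*` on edge-of-sphere validation slices (values < 0.10 indicate a
reliable model).

**Segmentation.** Each axial slice gets its own threshold: slice `TB` is
measured once, then threshold and contoured area are iterated to a fixed
point on the 1% grid, with the 133 mm² split deciding which model form
applies. The target volume is `Σ areaᵢ × slice thickness`.

## Worked example

`examples/calibrate_and_fit.py` simulates three phantom acquisitions
(prepared contrasts 4.2, 8.1, 16.6; 8 mm smoothing), finds the optimal
per-sphere thresholds and fits the split models:

```
18 calibration records, 0 unresolved

sphere    area(mm2)   TB      TS(%)
  10 mm       78.5    2.40     75
  13 mm      132.7    3.15     63
  17 mm      227.0    3.77     57
  ...
  37 mm     1075.2   16.65     47

fitted models (TS percent):
  A <= 133 mm2: intercept=+68.830  inv_tb=+41.274  area=-0.145   adjusted R2 = 0.98
  A > 133 mm2: intercept=+42.211  inv_tb=+54.981   adjusted R2 = 0.95
```

Reading the table: the 10 mm sphere needs a 75% threshold at a measured
contrast of 2.4 — partial volume has eaten most of its apparent contrast
(prepared ratio was 4.2) — while the 37 mm sphere at high contrast is
correctly delineated at 47%. The fitted coefficients carry the same
structure as the built-in published models: thresholds fall with area and
with contrast (positive coefficient on 1/TB).

The other examples cover simulation and TB measurement
(`simulate_phantom.py`), model evaluation at clinical operating points
(`predict_thresholds.py`), slice-specific segmentation of a sphere
(`segment_sphere.py`) and the ANCOVA comparison of reconstruction
settings (`reconstruction_factors.py`). A thin CLI mirrors the pipeline:
`petthresh simulate | measure-tb | calibrate | fit | segment | report`.

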