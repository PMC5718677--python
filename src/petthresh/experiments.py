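"""Reproducible study-scale experiments.

Each function here runs one self-contained computational experiment with
all randomness derived from a single seed:

* parameter recovery — synthesize calibration records from the published
  pooled threshold models and check that OLS refits recover the printed
  coefficients;
* ANCOVA behavior — a balanced smoothing x iterations design with a true
  smoothing effect and a null iteration effect, replicated to measure how
  often each factor is called significant;
* end-to-end volume recovery — simulate, self-calibrate and segment
  spheres, comparing delineated volumes against the analytic truth;
* reliability — cross-validation shrinkage of the large-area model on an
  edge-slice validation sample.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass

import numpy as np

from .calibration import SearchSettings, ThresholdRecord, calibrate_scheme
from .phantom import default_iec_spec, generate_threshold_dataset, simulate_phantom
from .regression import (
    ancova,
    fit_linear_model,
    fit_split_models,
    published_models,
    shrinkage_cross_validation,
)
from .roi import SliceROI, nema_background_pattern
from .segmentation import relative_difference, segment_volume
from .workbench import derive_seeds

__all__ = [
    "RecoveredCoefficient",
    "recover_pooled_small",
    "recover_pooled_large",
    "ancova_factor_detection",
    "volume_recovery",
    "edge_validation_shrinkage",
    "NOISE_SD_SMALL",
    "NOISE_SD_LARGE",
]

#: Residual scatter (percent threshold) of the pooled small-area model:
#: square root of the reported error mean square (31.5) of its ANCOVA.
NOISE_SD_SMALL = math.sqrt(31.5)
#: Residual scatter of the pooled large-area model (error mean square 7.4).
NOISE_SD_LARGE = math.sqrt(7.4)


@dataclass(frozen=True)
class RecoveredCoefficient:
    name: str
    reference: float
    estimate: float
    stderr: float

    @property
    def within_2se(self) -> bool:
        return abs(self.estimate - self.reference) <= 2.0 * self.stderr


def _design_grid(areas, tbs, fwhms):
    return [
        {"area_mm2": a, "tb": tb, "fwhm_mm": f}
        for a, tb, f in itertools.product(areas, tbs, fwhms)
    ]


def recover_pooled_small(seed: int, n_target: int = 300) -> dict[str, RecoveredCoefficient]:
    """Parameter recovery for the pooled small-area model.

    Records are generated on a grid A in [13, 133] mm², TB in [1.5, 70]
    (log-spaced, matching the calibrated contrast range), FWHM in
    {4, 6, 8} mm, with responses from the published coefficients plus
    Gaussian noise of sd sqrt(31.5); the OLS refit on (area, 1/TB, FWHM)
    is compared coefficient by coefficient.
    """
    model = published_models().pooled.small
    per_fwhm = max(int(round(n_target / 3)), 4)
    n_a = max(int(round(math.sqrt(per_fwhm))), 2)
    n_tb = max(per_fwhm // n_a, 2)
    grid = _design_grid(
        np.linspace(13.0, 133.0, n_a),
        np.geomspace(1.5, 70.0, n_tb),
        (4.0, 6.0, 8.0),
    )
    records = generate_threshold_dataset(model, grid, NOISE_SD_SMALL, seed)
    fit = fit_linear_model(records, ("area", "inv_tb", "fwhm"))
    return {
        name: RecoveredCoefficient(
            name, model.coefficients[name], fit.coefficients[name], fit.stderr[name]
        )
        for name in ("intercept", "area", "inv_tb", "fwhm")
    }


def recover_pooled_large(seed: int, n_target: int = 300) -> dict[str, RecoveredCoefficient]:
    """Parameter recovery for the pooled large-area model (TS on 1/TB and
    FWHM; noise sd sqrt(7.4))."""
    model = published_models().pooled.large
    n_tb = max(int(round(n_target / 3)), 4)
    grid = [
        {"area_mm2": None, "tb": tb, "fwhm_mm": f}
        for tb, f in itertools.product(np.geomspace(1.5, 70.0, n_tb), (4.0, 6.0, 8.0))
    ]
    records = generate_threshold_dataset(model, grid, NOISE_SD_LARGE, seed)
    fit = fit_linear_model(records, ("inv_tb", "fwhm"))
    return {
        name: RecoveredCoefficient(
            name, model.coefficients[name], fit.coefficients[name], fit.stderr[name]
        )
        for name in ("intercept", "inv_tb", "fwhm")
    }


def ancova_factor_detection(
    seed: int,
    n_replicates: int = 100,
    *,
    smoothing_slope: float = 2.82,
    alpha_smoothing: float = 0.01,
    alpha_iterations: float = 0.05,
) -> dict[str, float]:
    """Fraction of replicates in which ANCOVA detects the smoothing effect
    and (correctly) fails to detect the null iteration effect.

    Each replicate is a balanced 3 (smoothing: 4/6/8 mm) x 3 (iterations:
    16/32/64) design over an area x contrast grid; the response follows the
    small-area relation with a true smoothing slope (percent per mm, the
    published 2.82 by default), no iteration effect, and residual sd
    sqrt(31.5).
    """
    base = published_models().pooled.small.coefficients
    areas = np.linspace(20.0, 130.0, 6)
    tbs = np.geomspace(2.0, 50.0, 6)
    cells = [(f, it) for f in (4.0, 6.0, 8.0) for it in (16, 32, 64)]
    design = [
        (a, tb, f, it) for (f, it) in cells for a, tb in itertools.product(areas, tbs)
    ]
    seeds = derive_seeds(seed, n_replicates)
    hits_smoothing = 0
    null_iterations = 0
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        records = []
        for a, tb, f, it in design:
            ts = (
                base["intercept"]
                + base["area"] * a
                + base["inv_tb"] / tb
                + smoothing_slope * f
                + rng.normal(0.0, NOISE_SD_SMALL)
            )
            records.append(ThresholdRecord(float("nan"), a, tb, ts, it, f, "synthetic"))
        table = ancova(records)
        if table["Smoothing"].p < alpha_smoothing:
            hits_smoothing += 1
        if table["Iterations"].p > alpha_iterations:
            null_iterations += 1
    return {
        "smoothing_detected": hits_smoothing / n_replicates,
        "iterations_null_retained": null_iterations / n_replicates,
        "n_replicates": n_replicates,
    }


@dataclass(frozen=True)
class VolumeRecovery:
    diameter_mm: float
    prepared_tb: float
    volume_ml: float
    true_volume_ml: float

    @property
    def relative_error_percent(self) -> float:
        return relative_difference(self.volume_ml, self.true_volume_ml)


def volume_recovery(
    seed: int,
    *,
    tb_ratios: tuple[float, ...] = (4.0, 8.0, 16.0),
    diameters: tuple[float, ...] = (13.0, 17.0, 22.0, 28.0, 37.0),
    smoothing_fwhm: float = 8.0,
    noise_sd_fraction: float = 0.05,
) -> list[VolumeRecovery]:
    """Simulate, self-calibrate and segment: the full pipeline on spheres.

    One acquisition per prepared TB ratio; calibration uses edge-inclusive
    training (every slice with true area >= 15 mm²) so the small-area
    regime is sampled across its extent; the fitted per-scheme model pair
    then segments every sphere in every image over its true axial extent
    (the slices a co-registered CT would assign).  Returns one record per
    (sphere, TB) pair.
    """
    seeds = derive_seeds(seed, len(tb_ratios))
    images = []
    for tb, s in zip(tb_ratios, seeds):
        spec = default_iec_spec(
            tb,
            smoothing_fwhm=smoothing_fwhm,
            seed=s,
            sphere_diameters=diameters,
            noise_sd_fraction=noise_sd_fraction,
        )
        images.append(simulate_phantom(spec))

    scheme = (16, smoothing_fwhm)
    cal = calibrate_scheme(images, scheme, SearchSettings(), edge_training=True)
    models = fit_split_models(cal.records, pooled=False).per_scheme[scheme]

    out: list[VolumeRecovery] = []
    for (volume, truth), prepared in zip(images, tb_ratios):
        pattern = nema_background_pattern(volume, truth, truth.central_slice(0))
        for si, sph in enumerate(truth.spheres):
            csl = truth.central_slice(si)
            roi = SliceROI((sph.center[0], sph.center[1]), sph.internal_diameter, csl)
            background = pattern.concentric(min(sph.internal_diameter, 37.0))
            ks = [
                k for k in range(volume.shape[2]) if truth.slice_area_mm2(si, k) > 0
            ]
            result = segment_volume(
                volume, models, roi, background, smoothing_fwhm, (min(ks), max(ks) + 1)
            )
            out.append(
                VolumeRecovery(
                    diameter_mm=sph.internal_diameter,
                    prepared_tb=prepared,
                    volume_ml=result.volume_ml,
                    true_volume_ml=sph.true_volume_ml,
                )
            )
    return out


def edge_validation_shrinkage(
    seed: int,
    *,
    tb_ratios: tuple[float, ...] = (2.5, 4.2, 8.1, 16.6, 35.0, 70.0),
    smoothing_fwhm: float = 8.0,
) -> float:
    """Cross-validation shrinkage of the large-area model on an edge-slice
    validation sample (central slices train; off-center slices of the
    larger spheres validate)."""
    seeds = derive_seeds(seed, len(tb_ratios))
    images = []
    for tb, s in zip(tb_ratios, seeds):
        spec = default_iec_spec(tb, smoothing_fwhm=smoothing_fwhm, seed=s)
        images.append(simulate_phantom(spec))
    scheme = (16, smoothing_fwhm)
    cal = calibrate_scheme(images, scheme, SearchSettings(), include_validation=True)
    models = fit_split_models(cal.records, pooled=False).per_scheme[scheme]
    validation = [
        r for r in cal.records if r.role == "validation" and r.area_mm2 > models.area_split_mm2
    ]
    return shrinkage_cross_validation(models.large, validation)
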