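"""Optimal slice-threshold calibration.

For a target of known cross-sectional area, the optimal threshold TS is the
percentage of the in-slice maximum at which the auto-contoured area best
matches the true physical area: candidate levels are scanned in 1% steps
and a candidate is admissible when its area error is strictly below 10 mm².
The scan is exhaustive and deterministic: among admissible candidates the
absolute-error minimizer wins, with exact ties resolved to the center of the
largest contiguous plateau of minimizers.

Areas are measured by sub-voxel iso-contouring (marching squares on the
bilinearly interpolated slice) by default, because the 10 mm² tolerance is
only ~1.5 in-plane voxels at 2.6 mm pitch; plain voxel counting is retained
as an alternative estimator.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure

from .phantom import GroundTruth, ImageVolume, PhantomSpec
from .roi import ROISet, SliceROI, measure_tb, nema_background_pattern, roi_mask

__all__ = [
    "Contour",
    "ThresholdRecord",
    "SearchSettings",
    "ThresholdSearchResult",
    "CalibrationResult",
    "ContourError",
    "NoSolutionError",
    "autocontour_slice",
    "find_slice_threshold",
    "calibrate_scheme",
    "records_to_frame",
    "frame_to_records",
]

#: Cross-sectional area (mm²) separating the small-area and large-area
#: threshold models; equivalent to a 13 mm sphere diameter, set by the
#: resolution characteristics of the emulated scanner.
AREA_SPLIT_MM2 = 133.0

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class ContourError(ValueError):
    """No iso-contour can be formed on this slice."""


class NoSolutionError(ValueError):
    """No threshold on the scan grid meets the area tolerance."""

    def __init__(self, message: str, best_ts: float, best_error: float):
        super().__init__(message)
        self.best_ts = best_ts
        self.best_error = best_error


@dataclass(frozen=True)
class Contour:
    """Iso-contour of one slice: closed polyline(s) in mm and the enclosed
    area (outer boundary minus holes)."""

    slice_index: int
    iso_fraction: float
    polylines: tuple[np.ndarray, ...]
    area_mm2: float


@dataclass(frozen=True)
class ThresholdRecord:
    """One calibration observation: sphere identity, true cross-sectional
    area A, measured TB ratio, optimal threshold TS, and the reconstruction
    scheme (EM-equivalent iterations, smoothing FWHM)."""

    sphere_id_mm: float
    area_mm2: float
    tb: float
    ts_percent: float
    iterations: int
    fwhm_mm: float
    role: str = "training"  # training | validation | synthetic

    @property
    def low_contrast_flag(self) -> bool:
        """TB below 1 means the target is not hotter than background."""
        return self.tb < 1.0


@dataclass(frozen=True)
class SearchSettings:
    """Threshold-scan settings: step and area tolerance per the calibration
    protocol, plus the area-estimator mode."""

    step_percent: float = 1.0
    tolerance_mm2: float = 10.0
    area_mode: str = "subvoxel"  # subvoxel | voxel-count

    def __post_init__(self) -> None:
        if self.step_percent <= 0 or self.tolerance_mm2 <= 0:
            raise ValueError("step and tolerance must be > 0")
        if self.area_mode not in ("subvoxel", "voxel-count"):
            raise ValueError(f"unknown area mode {self.area_mode!r}")

    def ts_grid(self) -> np.ndarray:
        n = int(round(100.0 / self.step_percent))
        return np.round(np.arange(1, n + 1) * self.step_percent, 10)


@dataclass(frozen=True)
class ThresholdSearchResult:
    ts_percent: float
    area_mm2: float
    error_mm2: float


def _shoelace_mm2(poly: np.ndarray) -> float:
    """Signed area of a closed polygon given as (N, 2) mm coordinates."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _point_in_polygon(poly: np.ndarray, point: tuple[float, float]) -> bool:
    from matplotlib.path import Path

    return bool(Path(poly).contains_point(point))


def autocontour_slice(
    volume: ImageVolume,
    slice_index: int,
    ts_percent: float,
    search_roi: SliceROI,
    *,
    area_mode: str = "subvoxel",
) -> Contour:
    """Auto-contour one axial slice at a percentage-of-maximum iso-level.

    The level is ``ts_percent/100`` of the maximum intensity inside
    ``search_roi``; the contoured region is the 4-connected component of
    supra-level voxels containing that maximum.  In ``subvoxel`` mode the
    enclosed area comes from marching-squares contours of the bilinearly
    interpolated slice (holes subtracted); in ``voxel-count`` mode it is the
    component's voxel count times the in-plane voxel area.
    """
    if not 0 < ts_percent <= 100:
        raise ValueError("ts_percent must be in (0, 100]")
    sl = volume.values[:, :, slice_index]
    mask = roi_mask(volume, dataclasses.replace(search_roi, slice_index=slice_index))
    if not mask.any():
        raise ContourError("search ROI contains no voxels")
    vmax = float(sl[mask].max())
    if vmax <= 0:
        raise ContourError("slice maximum within the ROI is not positive")
    level = ts_percent / 100.0 * vmax

    supra = sl >= level
    labels, _ = ndimage.label(supra, structure=FOUR_CONNECTED)
    masked = np.where(mask, sl, -np.inf)
    max_idx = np.unravel_index(int(np.argmax(masked)), sl.shape)
    target_label = labels[max_idx]
    component = labels == target_label

    sx, sy = volume.voxel_spacing[0], volume.voxel_spacing[1]
    if area_mode == "voxel-count":
        area = float(component.sum()) * sx * sy
        return Contour(slice_index, ts_percent / 100.0, (), area)

    # suppress other supra-level components so marching squares traces only
    # the target component, then pad so every contour closes
    fill = min(float(sl.min()), level) - 1.0
    work = np.where(supra & ~component, fill, sl)
    work = np.pad(work, 1, constant_values=fill)
    contours = skmeasure.find_contours(work, level)
    if not contours:
        # iso-level at or above every interpolated value: degenerate contour
        return Contour(slice_index, ts_percent / 100.0, (), 0.0)

    def to_mm(c: np.ndarray) -> np.ndarray:
        out = np.empty_like(c)
        out[:, 0] = volume.origin[0] + (c[:, 0] - 1 + 0.5) * sx
        out[:, 1] = volume.origin[1] + (c[:, 1] - 1 + 0.5) * sy
        return out

    polys = [to_mm(c) for c in contours]
    max_mm = (
        volume.origin[0] + (max_idx[0] + 0.5) * sx,
        volume.origin[1] + (max_idx[1] + 0.5) * sy,
    )
    outer = None
    outer_area = 0.0
    for p in polys:
        a = abs(_shoelace_mm2(p))
        if _point_in_polygon(p, max_mm) and a > outer_area:
            outer, outer_area = p, a
    if outer is None:
        # max voxel exactly on the iso-level: zero-area degenerate contour
        return Contour(slice_index, ts_percent / 100.0, (), 0.0)
    area = outer_area
    kept = [outer]
    for p in polys:
        if p is outer:
            continue
        if _point_in_polygon(outer, tuple(p[0])) and abs(_shoelace_mm2(p)) < outer_area:
            area -= abs(_shoelace_mm2(p))
            kept.append(p)
    return Contour(slice_index, ts_percent / 100.0, tuple(kept), max(area, 0.0))


def find_slice_threshold(
    volume: ImageVolume,
    slice_index: int,
    true_area_mm2: float,
    search_roi: SliceROI,
    settings: SearchSettings = SearchSettings(),
) -> ThresholdSearchResult:
    """Exhaustive 1%-step scan for the slice-specific optimal threshold.

    Every candidate level on the step grid is contoured; candidates whose
    area differs from ``true_area_mm2`` by strictly less than the tolerance
    are admissible, and the absolute-error minimizer is returned (plateau
    ties resolved to the center of the largest contiguous run).  Raises
    :class:`NoSolutionError`, carrying the best achievable error, when no
    candidate is admissible.
    """
    if true_area_mm2 <= 0:
        raise ValueError("true_area_mm2 must be > 0")
    grid = settings.ts_grid()
    areas = np.full(grid.shape, np.nan)
    for i, ts in enumerate(grid):
        try:
            areas[i] = autocontour_slice(
                volume, slice_index, float(ts), search_roi, area_mode=settings.area_mode
            ).area_mm2
        except ContourError:
            continue
    errors = np.abs(areas - true_area_mm2)
    errors[np.isnan(errors)] = np.inf
    admissible = errors < settings.tolerance_mm2
    if not admissible.any():
        best = int(np.argmin(errors))
        raise NoSolutionError(
            f"no threshold within {settings.tolerance_mm2} mm² of {true_area_mm2} mm² "
            f"(best |error| {errors[best]:.1f} mm² at TS={grid[best]:g}%)",
            best_ts=float(grid[best]),
            best_error=float(errors[best]),
        )
    min_err = errors[admissible].min()
    minimizers = admissible & np.isclose(errors, min_err, rtol=0.0, atol=1e-9)
    # largest contiguous plateau of minimizers, central element
    idx = np.flatnonzero(minimizers)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    run = max(runs, key=len)
    pick = run[(len(run) - 1) // 2]
    return ThresholdSearchResult(
        ts_percent=float(grid[pick]),
        area_mm2=float(areas[pick]),
        error_mm2=float(errors[pick]),
    )


@dataclass
class CalibrationFailure:
    sphere_id_mm: float
    slice_index: int
    role: str
    best_ts: float
    best_error: float


@dataclass
class CalibrationResult:
    records: list[ThresholdRecord]
    failures: list[CalibrationFailure] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    @property
    def resolved_fraction(self) -> float:
        total = len(self.records) + len(self.failures)
        return len(self.records) / total if total else float("nan")


#: Axial slice offsets (in slices) used for the edge-of-sphere validation
#: sample of the larger spheres.
VALIDATION_SLICE_OFFSETS = (-4, -2, 2, 4)
#: Minimum true slice area (mm²) for a validation slice to be attempted.
MIN_VALIDATION_AREA_MM2 = 50.0
#: Minimum true slice area (mm²) for an edge-training slice (~2 in-plane
#: voxels; smaller cross-sections are unresolvable at any threshold).
MIN_EDGE_AREA_MM2 = 15.0


def calibrate_scheme(
    images: list[tuple[ImageVolume, GroundTruth]],
    scheme: tuple[int, float],
    settings: SearchSettings = SearchSettings(),
    *,
    include_validation: bool = False,
    edge_training: bool = False,
) -> CalibrationResult:
    """Build the calibration table for one reconstruction scheme.

    For each image and sphere, TB is measured on the central slice (target
    ROI of the sphere's physical internal diameter, background from the
    automatic NEMA pattern with concentric same-diameter ROIs) and the
    optimal TS found at the central, largest cross-section (role
    ``training``).  With ``include_validation``, off-center slices of
    spheres larger than the 133 mm² split contribute ``validation`` records.
    With ``edge_training``, every off-center slice with true area of at
    least 15 mm² contributes a ``training`` record instead — this samples
    the small-area regime across its full extent and matches the slice
    population the models later segment.  Unresolvable sphere/slice
    combinations are collected as failures, not raised.
    """
    iterations, fwhm = scheme
    result = CalibrationResult(records=[])
    for volume, truth in images:
        central = truth.central_slice(0)
        pattern37 = nema_background_pattern(volume, truth, central)
        for si, sph in enumerate(truth.spheres):
            csl = truth.central_slice(si)
            target = SliceROI((sph.center[0], sph.center[1]), sph.internal_diameter, csl)
            background = pattern37.concentric(min(sph.internal_diameter, 37.0))
            jobs = [(csl, truth.central_area_mm2(si), "training")]
            if edge_training:
                for k in range(volume.shape[2]):
                    if k == csl:
                        continue
                    a = truth.slice_area_mm2(si, k)
                    if a >= MIN_EDGE_AREA_MM2:
                        jobs.append((k, a, "training"))
            elif include_validation and truth.central_area_mm2(si) > AREA_SPLIT_MM2:
                for off in VALIDATION_SLICE_OFFSETS:
                    k = csl + off
                    if not 0 <= k < volume.shape[2]:
                        continue
                    a = truth.slice_area_mm2(si, k)
                    if a >= MIN_VALIDATION_AREA_MM2:
                        jobs.append((k, a, "validation"))
            for k, true_area, role in jobs:
                roi_k = dataclasses.replace(target, slice_index=k)
                tb = measure_tb(volume, roi_k, background)
                try:
                    found = find_slice_threshold(volume, k, true_area, roi_k, settings)
                except NoSolutionError as err:
                    result.failures.append(
                        CalibrationFailure(
                            sph.internal_diameter, k, role, err.best_ts, err.best_error
                        )
                    )
                    continue
                result.records.append(
                    ThresholdRecord(
                        sphere_id_mm=sph.internal_diameter,
                        area_mm2=true_area,
                        tb=tb,
                        ts_percent=found.ts_percent,
                        iterations=iterations,
                        fwhm_mm=fwhm,
                        role=role,
                    )
                )
    return result


RECORD_COLUMNS = ["sphere_id_mm", "area_mm2", "tb", "ts_percent", "iterations", "fwhm_mm", "role"]


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate records, adding the derived predictors ``inv_tb`` (1/TB) and
    ``contrast`` (1 - 1/TB)."""
    rows = [
        (r.sphere_id_mm, r.area_mm2, r.tb, r.ts_percent, r.iterations, r.fwhm_mm, r.role)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df["inv_tb"] = 1.0 / df["tb"]
    df["contrast"] = 1.0 - df["inv_tb"]
    return df


def frame_to_records(df: pd.DataFrame) -> list[ThresholdRecord]:
    return [
        ThresholdRecord(
            sphere_id_mm=float(row.sphere_id_mm),
            area_mm2=float(row.area_mm2),
            tb=float(row.tb),
            ts_percent=float(row.ts_percent),
            iterations=int(row.iterations),
            fwhm_mm=float(row.fwhm_mm),
            role=str(row.role),
        )
        for row in df.itertuples(index=False)
    ]
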