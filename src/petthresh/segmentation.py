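"""Slice-specific adaptive-threshold target delineation.

Each axial slice gets its own threshold: the slice TB ratio is measured
once, then threshold and contoured area are iterated to self-consistency —
the predicted TS depends on the contoured area (which model applies is
decided by the 133 mm² split), and the contoured area depends on TS.  TS is
quantized to the 1% calibration grid inside the loop, so the iteration
lives on a finite state space and must reach a fixed point or a cycle
within 100 steps; cycles are resolved by the visited threshold that is most
consistent with its own prediction.  The target volume is assembled as the
sum of per-slice areas times the slice thickness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .calibration import Contour, ContourError, autocontour_slice
from .phantom import ImageVolume
from .regression import ModelPair, PredictionFlags, ThresholdModel
from .roi import ROISet, SliceROI, measure_tb

__all__ = [
    "SliceSegmentation",
    "SegmentationResult",
    "SegmentationError",
    "predict_ts",
    "segment_slice",
    "segment_volume",
    "relative_difference",
]

MAX_ITERATIONS = 100

#: Contours smaller than ~3 in-plane voxels are below scanner resolution;
#: a fixed point this small signals degenerate near-top capture at very low
#: slice contrast, and the slice is re-resolved from the low-threshold side.
MIN_CONTOUR_AREA_MM2 = 20.0


class SegmentationError(ValueError):
    """Delineation failed for every requested slice."""


def predict_ts(
    model: ThresholdModel,
    *,
    tb: float,
    area: float | None = None,
    fwhm: float = 0.0,
) -> tuple[float, PredictionFlags]:
    """Predicted threshold (percent of slice max) with extrapolation/clip
    flags; thin wrapper over :meth:`ThresholdModel.predict`."""
    return model.predict(tb=tb, area=area, fwhm=fwhm)


@dataclass(frozen=True)
class SliceSegmentation:
    slice_index: int
    tb: float
    ts_percent: float
    contour: Contour | None
    area_mm2: float
    model_form: str
    iterations: int
    status: str  # fixed-point | cycle-resolved | failed
    extrapolated: bool = False

    @property
    def converged(self) -> bool:
        return self.status in ("fixed-point", "cycle-resolved")


@dataclass(frozen=True)
class SegmentationResult:
    slices: tuple[SliceSegmentation, ...]
    volume_ml: float
    label: str = "target"

    @property
    def failed_slices(self) -> tuple[int, ...]:
        return tuple(s.slice_index for s in self.slices if s.status == "failed")


def _grid_ts(ts: float, step: float = 1.0) -> float:
    """Quantize a predicted threshold to the calibration step grid in
    [1, 100]."""
    q = round(ts / step) * step
    return float(min(max(q, step), 100.0))


def segment_slice(
    volume: ImageVolume,
    slice_index: int,
    models: ModelPair,
    target_roi: SliceROI,
    background_rois: ROISet,
    fwhm: float,
    *,
    step_percent: float = 1.0,
    area_mode: str = "subvoxel",
) -> SliceSegmentation:
    """Delineate one slice by fixed-point threshold/area iteration.

    TB is measured once.  The iteration starts high, from the small-area
    model's area-free prediction (its value as the cross-section shrinks to
    zero, where partial-volume physics demands the most elevated
    threshold); at each step the slice is contoured at the current TS and
    the next TS is the prediction of the model selected by the current area
    against the 133 mm² split, quantized to the step grid.  Descending from
    the top lets genuinely small cross-sections settle at the small-model
    fixed point instead of being captured by the larger, lower-threshold
    contour of the blurred halo; large cross-sections fall through to the
    large-model fixed point.  Terminates on a repeated TS (fixed point) or
    a revisited state (cycle, resolved by minimal self-inconsistency
    |TS - prediction(area(TS))| among visited thresholds).
    """
    roi = dataclasses.replace(target_roi, slice_index=slice_index)
    tb = measure_tb(volume, roi, background_rois)

    def iterate(ts_init: float) -> SliceSegmentation:
        ts = _grid_ts(float(min(max(ts_init, 1.0), 100.0)), step_percent)
        visited: dict[float, tuple[float, float, str, bool, Contour]] = {}
        order: list[float] = []
        status = "failed"
        for it in range(1, MAX_ITERATIONS + 1):
            if ts not in visited:
                try:
                    contour = autocontour_slice(
                        volume, slice_index, ts, roi, area_mode=area_mode
                    )
                except ContourError:
                    return SliceSegmentation(
                        slice_index, tb, ts, None, 0.0, "none", it, "failed"
                    )
                model = models.select(contour.area_mm2)
                area_arg = contour.area_mm2 if model.form == "small_area" else None
                pred, flags = model.predict(tb=tb, area=area_arg, fwhm=fwhm)
                visited[ts] = (contour.area_mm2, pred, model.form, flags.extrapolated, contour)
                order.append(ts)
            area, pred, form, extrap, contour = visited[ts]
            nxt = _grid_ts(pred, step_percent)
            if nxt == ts:
                status = "fixed-point"
                break
            if nxt in visited:
                # cycle: keep the visited TS most consistent with its prediction
                ts = min(order, key=lambda t: abs(t - visited[t][1]))
                area, pred, form, extrap, contour = visited[ts]
                status = "cycle-resolved"
                break
            ts = nxt
        else:
            ts = min(order, key=lambda t: abs(t - visited[t][1]))
            area, pred, form, extrap, contour = visited[ts]
            status = "cycle-resolved"
        return SliceSegmentation(
            slice_index=slice_index,
            tb=tb,
            ts_percent=ts,
            contour=contour,
            area_mm2=area,
            model_form=form,
            iterations=len(order),
            status=status,
            extrapolated=extrap,
        )

    c = models.small.coefficients
    result = iterate(c["intercept"] + c.get("inv_tb", 0.0) / tb + c.get("fwhm", 0.0) * fwhm)
    if result.converged and result.area_mm2 < MIN_CONTOUR_AREA_MM2:
        # sub-resolution fixed point: re-resolve from the low-threshold side
        result = iterate(models.large.predict(tb=tb, fwhm=fwhm)[0])
    return result


def segment_volume(
    volume: ImageVolume,
    models: ModelPair,
    target_rois,
    background_rois: ROISet,
    fwhm: float,
    slice_range: tuple[int, int],
    *,
    label: str = "target",
    step_percent: float = 1.0,
    area_mode: str = "subvoxel",
) -> SegmentationResult:
    """Segment a contiguous axial slice range and assemble the volume.

    ``target_rois`` is either one :class:`SliceROI` template reused on
    every slice or a mapping ``slice_index -> SliceROI``.  Failed slices
    contribute zero area and are flagged; the volume in ml is
    sum(area_mm2) * slice thickness / 1000.
    """
    lo, hi = slice_range
    if hi <= lo:
        raise ValueError("slice range is empty")
    slices = []
    for k in range(lo, hi):
        roi = target_rois[k] if isinstance(target_rois, dict) else target_rois
        try:
            seg = segment_slice(
                volume, k, models, roi, background_rois, fwhm,
                step_percent=step_percent, area_mode=area_mode,
            )
        except (ContourError, ValueError):
            seg = SliceSegmentation(k, float("nan"), 0.0, None, 0.0, "none", 0, "failed")
        slices.append(seg)
    if all(s.status == "failed" for s in slices):
        raise SegmentationError("every slice in the range failed to segment")
    sz = volume.voxel_spacing[2]
    volume_ml = sum(s.area_mm2 for s in slices if s.converged) * sz / 1000.0
    return SegmentationResult(slices=tuple(slices), volume_ml=volume_ml, label=label)


def relative_difference(v_test: float, v_reference: float) -> float:
    """Percent difference of a test volume against a reference volume:
    100 * (test - reference) / reference."""
    if v_reference <= 0:
        raise ValueError("reference volume must be > 0")
    return 100.0 * (v_test - v_reference) / v_reference
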