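import math

import numpy as np
import pytest

import petthresh as pt
from petthresh.calibration import autocontour_slice
from petthresh.phantom import ImageVolume
from petthresh.regression import ModelPair, ThresholdModel
from petthresh.segmentation import (
    SegmentationError,
    predict_ts,
    relative_difference,
    segment_slice,
    segment_volume,
)

from .conftest import center_roi, gaussian_blob_volume


def flat_background_set(slice_indices, center=(10.0, 10.0), diameter=8.0):
    return pt.ROISet(
        tuple(
            pt.SliceROI(center, diameter, k, role="background") for k in slice_indices
        )
    )


def blob_volume(n_slices=3, sigma=6.0, peak=40.0, background=5.0):
    return gaussian_blob_volume(
        sigma_mm=sigma, peak=peak, size=81, n_slices=n_slices, background=background
    )


def constant_pair(small_ts, large_ts):
    small = ThresholdModel(
        form="small_area",
        coefficients={"intercept": small_ts, "area": 1e-9},
    )
    large = ThresholdModel(form="large_area", coefficients={"intercept": large_ts})
    return ModelPair(small=small, large=large)


class TestPredictTs:
    def test_pooled_small_hand_values(self, published):
        ts, _ = predict_ts(published.pooled.small, area=100.0, tb=4.0, fwhm=8.0)
        assert ts == pytest.approx(67.74, abs=1e-10)
        ts, _ = predict_ts(published.pooled.small, area=46.0, tb=2.9, fwhm=8.0)
        assert ts == pytest.approx(86.64, abs=0.005)

    def test_large_intercept_limit_is_flagged(self, published):
        ts, flags = predict_ts(published.pooled.large, tb=1e12, fwhm=0.0)
        assert ts == pytest.approx(33.13, abs=1e-6)
        assert flags.extrapolated

    def test_missing_area_for_small_form_rejected(self, published):
        with pytest.raises(ValueError):
            predict_ts(published.pooled.small, tb=4.0, fwhm=8.0)

    def test_result_clipped_to_percent_range(self, published):
        ts, flags = predict_ts(published.pooled.small, area=13.0, tb=1.5, fwhm=8.0)
        assert ts == 100.0
        assert flags.clipped


class TestSegmentSlice:
    def test_large_target_fixed_point_matches_large_prediction(self):
        vol = blob_volume()
        bg = flat_background_set([0])
        models = constant_pair(small_ts=50.0, large_ts=40.0)
        seg = segment_slice(vol, 0, models, center_roi(vol, 50.0), bg, 8.0)
        # every visited contour exceeds the split, so the iteration falls
        # through to the constant large-area prediction as its fixed point
        assert seg.status == "fixed-point"
        assert seg.model_form == "large_area"
        assert seg.ts_percent == 40.0
        assert seg.area_mm2 > 133.0

    def test_matches_exhaustive_self_consistency_oracle(self, published):
        vol = blob_volume(sigma=4.0, peak=30.0)
        bg = flat_background_set([0])
        roi = center_roi(vol, 40.0)
        seg = segment_slice(vol, 0, published.pooled, roi, bg, 8.0)
        tb = pt.measure_tb(vol, roi, bg)
        best_ts, best_gap = None, float("inf")
        for ts in range(1, 101):
            area = autocontour_slice(vol, 0, float(ts), roi).area_mm2
            model = published.pooled.select(area)
            pred, _ = model.predict(
                tb=tb, area=area if model.form == "small_area" else None, fwhm=8.0
            )
            gap = abs(ts - pred)
            if gap < best_gap:
                best_ts, best_gap = ts, gap
        assert seg.converged
        assert seg.ts_percent == pytest.approx(best_ts, abs=1.0)

    def test_constructed_two_cycle_is_resolved(self):
        # sigma = 6 mm blob: the 133 mm2 iso-area falls at ~55.5%; constant
        # models map 45% (area > split) -> 70% and 70% (area < split) -> 45%
        vol = blob_volume(sigma=6.0, peak=30.0, background=0.0)
        bg = flat_background_set([0])
        models = constant_pair(small_ts=45.0, large_ts=70.0)
        seg = segment_slice(vol, 0, models, center_roi(vol, 50.0), bg, 8.0)
        assert seg.status == "cycle-resolved"
        assert seg.ts_percent in (45.0, 70.0)

    def test_fixed_point_is_self_consistent(self, noisy_phantom, background_pattern, published):
        spec, volume, truth = noisy_phantom
        si = len(truth.spheres) - 1  # 37 mm
        sph = truth.spheres[si]
        roi = pt.SliceROI(
            (sph.center[0], sph.center[1]), sph.internal_diameter, truth.central_slice(si)
        )
        seg = segment_slice(
            volume, truth.central_slice(si), published.pooled, roi,
            background_pattern, 8.0,
        )
        assert seg.converged
        model = published.pooled.select(seg.area_mm2)
        pred, _ = model.predict(
            tb=seg.tb,
            area=seg.area_mm2 if model.form == "small_area" else None,
            fwhm=8.0,
        )
        assert abs(seg.ts_percent - pred) <= 1.0

    def test_raising_contrast_never_raises_threshold(self, published):
        vol = blob_volume(sigma=6.0, peak=30.0)
        bg = flat_background_set([0])
        roi = center_roi(vol, 50.0)
        boosted = ImageVolume(
            5.0 + 2.0 * (vol.values - 5.0), vol.voxel_spacing
        )
        ts_low = segment_slice(vol, 0, published.pooled, roi, bg, 8.0).ts_percent
        ts_high = segment_slice(boosted, 0, published.pooled, roi, bg, 8.0).ts_percent
        assert ts_high <= ts_low


class TestSegmentVolume:
    def test_volume_is_sum_of_slabs(self):
        # three binary-disk slices of known areas ~ (46, 60, 72) mm2 at
        # 2 mm thickness -> about 0.356 ml
        radii = [math.sqrt(a / math.pi) for a in (46.0, 60.0, 72.0)]
        size = 41
        x = np.arange(size) + 0.5
        c = size / 2.0
        slices = []
        for r in radii:
            d2 = (x[:, None] - c) ** 2 + (x[None, :] - c) ** 2
            slices.append(np.where(d2 <= r * r, 10.0, 1.0))
        vol = ImageVolume(np.stack(slices, axis=-1), (1.0, 1.0, 2.0))
        bg = flat_background_set([0, 1, 2], center=(5.0, 5.0), diameter=6.0)
        models = constant_pair(small_ts=50.0, large_ts=50.0)
        result = segment_volume(
            vol, models, center_roi(vol, 20.0), bg, 8.0, (0, 3)
        )
        assert result.volume_ml == pytest.approx(0.356, rel=0.05)
        assert result.volume_ml == pytest.approx(
            sum(s.area_mm2 for s in result.slices) * 2.0 / 1000.0
        )

    def test_subrange_volumes_are_additive(self, published):
        vol = blob_volume(n_slices=4)
        bg = flat_background_set([0, 1, 2, 3])
        roi = center_roi(vol, 50.0)
        full = segment_volume(vol, published.pooled, roi, bg, 8.0, (0, 4))
        parts = [
            segment_volume(vol, published.pooled, roi, bg, 8.0, (a, b))
            for a, b in ((0, 2), (2, 4))
        ]
        assert full.volume_ml == pytest.approx(sum(p.volume_ml for p in parts))

    def test_empty_slice_range_rejected(self, published):
        vol = blob_volume()
        with pytest.raises(ValueError):
            segment_volume(
                vol, published.pooled, center_roi(vol, 50.0),
                flat_background_set([0]), 8.0, (2, 2),
            )

    def test_all_slices_failing_raises(self, published):
        vol = ImageVolume(np.zeros((30, 30, 2)), (1.0, 1.0, 2.0))
        with pytest.raises(SegmentationError):
            segment_volume(
                vol, published.pooled, center_roi(vol, 20.0),
                flat_background_set([0, 1], center=(5.0, 5.0), diameter=6.0),
                8.0, (0, 2),
            )


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "test_ml,ref_ml,expected,digits",
        [
            (0.8, 0.9, -11.0, 0),
            (2.91, 3.16, -8.0, 0),
            (268.6, 287.9, -6.7, 1),
            (5.0, 5.0, 0.0, 6),
        ],
    )
    def test_printed_patient_values(self, test_ml, ref_ml, expected, digits):
        assert round(relative_difference(test_ml, ref_ml), digits) == pytest.approx(
            expected
        )

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(1.0, 0.0)
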