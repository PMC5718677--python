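import itertools
import math

import numpy as np
import pandas as pd
import pytest

import petthresh as pt
from petthresh.calibration import ThresholdRecord
from petthresh.regression import (
    DesignError,
    FitError,
    InsufficientDataError,
    ThresholdModel,
    adjusted_factor_means,
    ancova,
    fit_linear_model,
    fit_split_models,
    shrinkage_cross_validation,
)


def frame(n=30, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "area_mm2": rng.uniform(20, 400, n),
            "tb": rng.uniform(1.5, 30, n),
            "fwhm_mm": rng.choice([4.0, 6.0, 8.0], n),
            "iterations": rng.choice([16, 32, 64], n),
            "role": "synthetic",
        }
    )
    df["ts_percent"] = rng.uniform(30, 90, n)
    return df


class TestLinearFit:
    def test_noiseless_records_fit_exactly(self):
        df = frame(40, 1)
        df["ts_percent"] = 2.0 + 3.0 * df["area_mm2"] - 0.5 * df["tb"]
        fit = fit_linear_model(df, ("area_mm2", "tb"))
        assert fit.coefficients["intercept"] == pytest.approx(2.0, abs=1e-8)
        assert fit.coefficients["area_mm2"] == pytest.approx(3.0, abs=1e-10)
        assert fit.coefficients["tb"] == pytest.approx(-0.5, abs=1e-10)
        assert fit.r2_adj == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        df = frame(20, 2)
        fit = fit_linear_model(df, ("area", "inv_tb", "fwhm"))
        df = df.assign(inv_tb=1.0 / df.tb)
        X = np.column_stack(
            [np.ones(len(df)), df.area_mm2, df.inv_tb, df.fwhm_mm]
        )
        y = df.ts_percent.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = [
            fit.coefficients[k] for k in ("intercept", "area", "inv_tb", "fwhm")
        ]
        np.testing.assert_allclose(got, beta, rtol=1e-8)

    def test_single_predictor_std_beta_equals_correlation(self):
        df = frame(25, 3)
        fit = fit_linear_model(df, ("area",))
        r = np.corrcoef(df.area_mm2, df.ts_percent)[0, 1]
        assert fit.std_beta["area"] == pytest.approx(r, abs=1e-10)
        assert math.copysign(1, fit.std_beta["area"]) == math.copysign(
            1, fit.coefficients["area"]
        )

    def test_adjusted_r2_never_exceeds_r2(self):
        for seed in range(5):
            fit = fit_linear_model(frame(15, seed), ("area", "inv_tb"))
            assert fit.r2_adj <= fit.r2

    def test_too_few_records_rejected(self):
        with pytest.raises(FitError):
            fit_linear_model(frame(3, 0), ("area", "inv_tb", "fwhm"))

    def test_rank_deficiency_rejected(self):
        df = frame(20, 4)
        df["fwhm_mm"] = 6.0  # constant predictor
        with pytest.raises(FitError):
            fit_linear_model(df, ("area", "fwhm"))

    def test_contrast_and_inv_tb_parameterizations_are_equivalent(self):
        df = frame(40, 5)
        fit_c = fit_linear_model(df, ("area", "contrast"))
        fit_i = fit_linear_model(df, ("area", "inv_tb"))
        # TS = b0 + bc (1 - 1/TB) = (b0 + bc) - bc / TB
        assert fit_i.coefficients["intercept"] == pytest.approx(
            fit_c.coefficients["intercept"] + fit_c.coefficients["contrast"], abs=1e-8
        )
        assert fit_i.coefficients["inv_tb"] == pytest.approx(
            -fit_c.coefficients["contrast"], abs=1e-10
        )
        pred_c = (
            fit_c.coefficients["intercept"]
            + fit_c.coefficients["area"] * df.area_mm2
            + fit_c.coefficients["contrast"] * (1 - 1 / df.tb)
        )
        pred_i = (
            fit_i.coefficients["intercept"]
            + fit_i.coefficients["area"] * df.area_mm2
            + fit_i.coefficients["inv_tb"] / df.tb
        )
        np.testing.assert_allclose(pred_c, pred_i, atol=1e-10)


def records_from_model(model, grid, noise_sd, seed, iterations=16):
    recs = pt.generate_threshold_dataset(model, grid, noise_sd, seed)
    return [
        ThresholdRecord(r.sphere_id_mm, r.area_mm2, r.tb, r.ts_percent, iterations, r.fwhm_mm, "training")
        for r in recs
    ]


class TestSplitModels:
    def plane_records(self):
        small = ThresholdModel(
            form="small_area",
            coefficients={"intercept": 80.0, "area": -0.25, "inv_tb": 50.0, "fwhm": 2.0},
        )
        large = ThresholdModel(
            form="large_area", coefficients={"intercept": 35.0, "inv_tb": 60.0, "fwhm": 0.5}
        )
        grid_s = [
            {"area_mm2": a, "tb": tb, "fwhm_mm": f}
            for a, tb, f in itertools.product(
                np.linspace(20, 130, 5), np.linspace(2, 20, 4), (4.0, 6.0, 8.0)
            )
        ]
        grid_l = [
            {"area_mm2": a, "tb": tb, "fwhm_mm": f}
            for a, tb, f in itertools.product(
                np.linspace(150, 900, 5), np.linspace(2, 20, 4), (4.0, 6.0, 8.0)
            )
        ]
        return (
            records_from_model(small, grid_s, 0.0, 0)
            + records_from_model(large, grid_l, 0.0, 0)
        )

    def test_noiseless_plane_recovered_exactly(self):
        models = fit_split_models(self.plane_records())
        ps = models.pooled.small.coefficients
        assert ps["intercept"] == pytest.approx(80.0, abs=1e-7)
        assert ps["area"] == pytest.approx(-0.25, abs=1e-9)
        assert ps["inv_tb"] == pytest.approx(50.0, abs=1e-7)
        assert ps["fwhm"] == pytest.approx(2.0, abs=1e-8)
        pl = models.pooled.large.coefficients
        assert pl["intercept"] == pytest.approx(35.0, abs=1e-7)
        assert pl["inv_tb"] == pytest.approx(60.0, abs=1e-7)
        # calibration ranges recorded from the data extent
        assert models.pooled.small.ranges["area"] == pytest.approx((20.0, 130.0))

    def test_missing_regime_raises_named_error(self):
        records = [r for r in self.plane_records() if r.area_mm2 > 133.0]
        with pytest.raises(FitError, match="small_area"):
            fit_split_models(records)

    def test_pooled_fit_requires_multiple_smoothing_levels(self):
        records = [r for r in self.plane_records() if r.fwhm_mm == 8.0]
        with pytest.raises(FitError, match="fwhm|smoothing"):
            fit_split_models(records)
        # per-scheme fits still succeed without pooling
        models = fit_split_models(records, pooled=False)
        assert models.pooled is None
        assert (16, 8.0) in models.per_scheme


class TestPublishedModels:
    def test_pooled_small_hand_evaluation(self, published):
        ts, flags = published.pooled.small.predict(area=100.0, tb=4.0, fwhm=8.0)
        assert ts == pytest.approx(67.74, abs=1e-10)
        assert not flags.extrapolated

    def test_pooled_large_intercept_limit_flags_extrapolation(self, published):
        ts, flags = published.pooled.large.predict(tb=1e12, fwhm=0.0)
        assert ts == pytest.approx(33.13, abs=1e-6)
        assert flags.extrapolated

    def test_pooled_large_hand_evaluation(self, published):
        ts, _ = published.pooled.large.predict(tb=2.0, fwhm=6.0)
        assert ts == pytest.approx(66.87, abs=0.01)

    def test_per_scheme_canonical_conversion(self, published):
        # contrast form TS = 127.9 - 0.23 A - 48.7 (1 - 1/TB) re-expressed
        # on 1/TB: intercept 79.2, inv_tb +48.7
        model = published.per_scheme[(16, 8.0)].small
        assert model.coefficients["intercept"] == pytest.approx(127.9 - 48.7)
        assert model.coefficients["inv_tb"] == pytest.approx(48.7)
        assert model.coefficients["area"] == pytest.approx(-0.23)
        large = published.per_scheme[(16, 8.0)].large
        assert large.coefficients["intercept"] == pytest.approx(104.8 - 68.2)
        assert large.r2_adj == pytest.approx(0.94)


def balanced_records(seed, smoothing_slope=2.82, iteration_slope=0.0, noise_sd=5.6):
    rng = np.random.default_rng(seed)
    records = []
    for f, it in itertools.product((4.0, 6.0, 8.0), (16, 32, 64)):
        for a, tb in itertools.product(np.linspace(20, 130, 4), np.linspace(2, 20, 4)):
            ts = (
                55.94
                - 0.25 * a
                + 56.96 / tb
                + smoothing_slope * f
                + iteration_slope * it
                + rng.normal(0, noise_sd)
            )
            records.append(ThresholdRecord(float("nan"), a, tb, ts, it, f, "synthetic"))
    return records


class TestAncova:
    def test_sum_of_squares_decomposition(self):
        records = balanced_records(0)
        table = ancova(records)
        df = pt.calibration.records_to_frame(records)
        total_ss = ((df.ts_percent - df.ts_percent.mean()) ** 2).sum()
        assert sum(r.ss for r in table.rows) == pytest.approx(total_ss, rel=1e-10)
        err = table.error
        assert err.ms == pytest.approx(err.ss / err.df)

    def test_balanced_design_factor_ss_order_independent(self):
        records = balanced_records(1)
        t1 = ancova(records, factors=("smoothing", "iterations"))
        t2 = ancova(records, factors=("iterations", "smoothing"))
        assert t1["Smoothing"].ss == pytest.approx(t2["Smoothing"].ss, rel=1e-9)
        assert t1["Iterations"].ss == pytest.approx(t2["Iterations"].ss, rel=1e-9)

    def test_detects_smoothing_and_retains_iteration_null(self):
        table = ancova(balanced_records(2))
        assert table["Smoothing"].p < 0.01
        assert table["Iterations"].p > 0.05
        assert table["Smoothing*Iterations"].p > 0.01

    def test_null_effects_give_unit_mean_f(self):
        fs = []
        for seed in range(20):
            table = ancova(balanced_records(seed, smoothing_slope=0.0))
            fs.append(table["Smoothing"].f)
            fs.append(table["Iterations"].f)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.45)

    def test_singleton_factor_interaction_rejected(self):
        records = [r for r in balanced_records(3) if r.fwhm_mm == 8.0]
        with pytest.raises(DesignError):
            ancova(records)

    def test_empty_cell_rejected(self):
        records = [
            r
            for r in balanced_records(4)
            if not (r.fwhm_mm == 8.0 and r.iterations == 64)
        ]
        with pytest.raises(DesignError):
            ancova(records)

    def test_adjusted_means_share_ci_width_on_balanced_design(self):
        records = balanced_records(5)
        means = adjusted_factor_means(records, "smoothing")
        widths = means.ci_high - means.ci_low
        assert widths.max() == pytest.approx(widths.min(), rel=1e-9)
        # more smoothing demands a higher threshold
        assert means.adjusted_mean.is_monotonic_increasing


class TestShrinkage:
    def model(self):
        return ThresholdModel(
            form="large_area",
            coefficients={"intercept": 35.0, "inv_tb": 60.0},
            r2_adj=0.92,
        )

    def validation(self, noise_sd, seed=0, n=40):
        rng = np.random.default_rng(seed)
        records = []
        for tb in np.linspace(1.5, 30, n):
            ts = 35.0 + 60.0 / tb + rng.normal(0, noise_sd)
            records.append(ThresholdRecord(37.0, 500.0, tb, ts, 16, 8.0, "validation"))
        return records

    def test_perfect_validation_gives_nonpositive_shrinkage(self):
        s = shrinkage_cross_validation(self.model(), self.validation(0.0))
        assert s == pytest.approx(0.92 - 1.0)
        assert s <= 0

    def test_pure_noise_validation_shrinks_to_r2(self):
        rng = np.random.default_rng(1)
        records = [
            ThresholdRecord(37.0, 500.0, tb, rng.uniform(30, 90), 16, 8.0, "validation")
            for tb in np.linspace(1.5, 30, 200)
        ]
        s = shrinkage_cross_validation(self.model(), records)
        assert s == pytest.approx(0.92, abs=0.1)

    def test_too_few_records_rejected(self):
        with pytest.raises(InsufficientDataError):
            shrinkage_cross_validation(self.model(), self.validation(1.0)[:2])
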