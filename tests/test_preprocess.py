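"""Censoring, linear conversion, loess/quantile normalization, CV metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maidflow import (
    ConfigurationError,
    PreprocessParams,
    ValidationError,
    ct_to_linear,
    ct_to_signal,
    cv,
    loess_normalize,
    quantile_scale,
    relative_quantify,
)
from maidflow.design import Platform, StudyDesign
from maidflow.errors import MaidflowError
from maidflow.matrix import LongitudinalMatrix

from conftest import make_design, make_matrix


class TestCtToLinear:
    def test_detection_limit_maps_to_floor_signal(self, params):
        # one significant figure: 0.004 at the Ct-38 limit
        assert round(ct_to_signal(38.0, params), 3) == 0.004

    def test_ct20_maps_to_953(self, params):
        assert int(ct_to_signal(20.0, params)) == 953

    def test_undetermined_is_censored_to_floor_and_flagged(self, params):
        design = make_design()
        ct = make_matrix(np.array([[45.0, 30.0, 30.0, 30.0]]), design, scale="ct")
        lin = ct_to_linear(ct, params)
        col = design.ordered_columns()[0]
        assert lin.values.iloc[0][col] == pytest.approx(ct_to_signal(38.0, params))
        assert not lin.detection_mask.iloc[0][col]
        assert lin.detection_mask.iloc[0][design.ordered_columns()[1]]

    @given(st.floats(min_value=1.0, max_value=37.0))
    @settings(max_examples=25, deadline=None)
    def test_one_cycle_doubles_the_signal(self, ct):
        assert ct_to_signal(ct - 1.0) == pytest.approx(2.0 * ct_to_signal(ct), rel=1e-12)

    def test_strictly_decreasing_below_the_limit(self):
        cts = np.linspace(1, 37.9, 200)
        sig = np.array([ct_to_signal(c) for c in cts])
        assert (np.diff(sig) < 0).all()

    def test_negative_ct_rejected(self, params):
        design = make_design()
        ct = make_matrix(np.array([[-1.0, 30.0, 30.0, 30.0]]), design, scale="ct")
        with pytest.raises(ValidationError, match="negative"):
            ct_to_linear(ct, params)


class TestLoess:
    def test_identical_samples_are_left_fixed(self, params):
        rng = np.random.default_rng(3)
        design = make_design(n_patients=1, time_points=("baseline", "t48h", "t96h", "m1"))
        col = 2.0 ** rng.normal(2, 2, 200)
        m = make_matrix(np.tile(col[:, None], (1, 4)), design)
        out = loess_normalize(m, params)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy(), rtol=1e-10)

    def test_constant_offset_pair_is_equalized(self, params):
        # sample j = 2 × sample i: after normalization the median log-ratio is 0
        rng = np.random.default_rng(4)
        design = make_design(n_patients=1, time_points=("baseline", "t48h"))
        base = 2.0 ** rng.normal(3, 2, 300)
        m = make_matrix(np.column_stack([base, 2.0 * base]), design)
        out = loess_normalize(m, params)
        logr = np.log2(out.values.iloc[:, 1] / out.values.iloc[:, 0])
        assert abs(np.median(logr)) < 1e-6

    def test_intensity_dependent_bow_is_reduced_per_decile(self):
        # 384 features × 4 samples with a slow sinusoidal M(A) distortion;
        # a finer span lets the local fits track one bow period
        rng = np.random.default_rng(5)
        params = PreprocessParams(loess_span=0.3)
        design = make_design(n_patients=1, time_points=("baseline", "t48h", "t96h", "m1"))
        a = rng.uniform(0, 12, 384)
        log2x = np.tile(a[:, None], (1, 4)) + rng.normal(0, 0.1, (384, 4))
        log2x[:, 1] += 0.5 * np.sin(a / 2.0)  # bow on one sample
        m = make_matrix(2.0 ** log2x, design)
        out = loess_normalize(m, params)

        def decile_medians(mat):
            lx = np.log2(mat)
            mm = lx[:, 1] - lx[:, 0]
            aa = 0.5 * (lx[:, 1] + lx[:, 0])
            order = np.argsort(aa)
            return np.array([np.abs(np.median(mm[c])) for c in np.array_split(order, 10)])

        before = decile_medians(m.values.to_numpy())
        after = decile_medians(out.values.to_numpy())
        material = before > 0.05  # deciles where the bow is above noise
        assert material.sum() >= 7
        assert (after[material] < before[material]).all()
        assert after.mean() < before.mean()

    def test_group_with_single_sample_rejected(self, params):
        design = StudyDesign(
            patients=("P1",),
            time_points=("baseline", "t48h"),
            sample_map={"a": ("P1", "baseline")},
        )
        m = LongitudinalMatrix(
            values=pd.DataFrame({"a": [1.0, 2.0]}, index=["f0", "f1"]),
            scale="linear",
            design=design,
        )
        with pytest.raises(ConfigurationError, match=">= 2"):
            loess_normalize(m, params)


class TestQuantileScale:
    def _two_patient_matrix(self):
        # patient 1 pooled values all 100 → 95% quantile 100; patient 2 all 400
        design = make_design(n_patients=2, time_points=("baseline", "t48h"))
        vals = np.column_stack(
            [np.full(10, 100.0), np.full(10, 100.0), np.full(10, 400.0), np.full(10, 400.0)]
        )
        return design, make_matrix(vals, design)

    def test_hand_computed_factors_and_target(self, params):
        design, m = self._two_patient_matrix()
        out = quantile_scale(m, params)
        # common target 200 → factors 2.0 and 0.5
        np.testing.assert_allclose(out.values["Pat1_baseline"], 200.0)
        np.testing.assert_allclose(out.values["Pat2_baseline"], 200.0)

    def test_quantiles_equal_after_scaling(self, params):
        rng = np.random.default_rng(6)
        design = make_design(n_patients=3, time_points=("baseline", "t48h"))
        vals = 2.0 ** rng.normal(4, 2, (100, 6)) * np.array([1, 1, 5, 5, 0.2, 0.2])
        m = make_matrix(vals, design)
        out = quantile_scale(m, params)
        qs = [
            np.quantile(out.values[[f"{p}_baseline", f"{p}_t48h"]].to_numpy(), 0.95)
            for p in design.patients
        ]
        assert max(qs) - min(qs) < 1e-9

    def test_idempotent(self, params):
        rng = np.random.default_rng(7)
        design = make_design(n_patients=3, time_points=("baseline", "t48h"))
        m = make_matrix(2.0 ** rng.normal(4, 2, (100, 6)), design)
        once = quantile_scale(m, params)
        twice = quantile_scale(once, params)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), rtol=1e-9
        )

    def test_single_patient_is_left_unscaled(self, params):
        design = make_design(n_patients=1, time_points=("baseline", "t48h"))
        m = make_matrix(np.array([[10.0, 20.0], [30.0, 40.0]]), design)
        out = quantile_scale(m, params)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())


class TestRelativeQuantify:
    def _single_tube(self, feature_ct, hk_ct=24.0, reps=3):
        patients = ("P1",)
        tps = ("baseline", "m1")
        sample_map = {
            f"P1_{t}_r{r}": ("P1", t) for t in tps for r in range(1, reps + 1)
        }
        design = StudyDesign(
            patients=patients,
            time_points=tps,
            sample_map=sample_map,
            platform=Platform.TAQMAN_SINGLE,
        )
        cols = {c: [feature_ct, hk_ct] for c in sample_map}
        values = pd.DataFrame(cols, index=["miR-t", "hsa-miR-191-5p"])
        return LongitudinalMatrix(values=values, scale="ct", design=design)

    def test_feature_equal_to_housekeeper_reports_1000(self, params):
        out = relative_quantify(self._single_tube(24.0), params)
        assert out.values.loc["miR-t"].to_numpy() == pytest.approx(1000.0)

    def test_one_cycle_above_housekeeper_halves(self, params):
        out = relative_quantify(self._single_tube(25.0), params)
        assert out.values.loc["miR-t"].to_numpy() == pytest.approx(500.0)

    def test_triplicate_mean_ct_is_used(self, params):
        m = self._single_tube(24.0)
        m.values.loc["miR-t", ["P1_baseline_r1", "P1_baseline_r2", "P1_baseline_r3"]] = [30.0, 30.5, 31.0]
        out = relative_quantify(m, params)
        expected = 1000.0 * 2.0 ** (24.0 - 30.5)
        assert out.values.loc["miR-t", "P1_baseline"] == pytest.approx(expected)

    def test_missing_housekeeper_is_hard_error(self, params):
        m = self._single_tube(24.0)
        m.values.drop(index="hsa-miR-191-5p", inplace=True)
        m.detection_mask.drop(index="hsa-miR-191-5p", inplace=True)
        with pytest.raises(MaidflowError, match="housekeeping"):
            relative_quantify(m, params)


class TestCV:
    def test_constant_feature_has_zero_cv(self):
        design = make_design(n_patients=2, time_points=("baseline", "t48h"))
        m = make_matrix(np.array([[5.0, 5.0, 5.0, 5.0]]), design)
        series, mean_cv = cv(m)
        assert series.iloc[0] == 0.0 and mean_cv == 0.0

    def test_one_two_three_has_cv_one_half(self):
        design = make_design(n_patients=1, time_points=("baseline", "t48h", "m1"))
        m = make_matrix(np.array([[1.0, 2.0, 3.0]]), design)
        series, _ = cv(m)
        assert series.iloc[0] == pytest.approx(0.5)

    def test_zero_mean_feature_excluded_from_mean_cv(self):
        design = make_design(n_patients=2, time_points=("baseline", "t48h"))
        m = make_matrix(np.array([[0.0, 0.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0]]), design)
        series, mean_cv = cv(m)
        assert np.isnan(series.iloc[0])
        assert mean_cv == pytest.approx(series.iloc[1])

    def test_loess_reduces_mean_cv_under_sample_biases(self, params):
        rng = np.random.default_rng(8)
        design = make_design(n_patients=1, time_points=("baseline", "t48h", "t96h", "m1"))
        log2x = rng.normal(4, 2, (300, 1)) + rng.normal(0, 0.2, (300, 4))
        log2x += np.array([0.0, 0.8, -0.6, 0.4])  # multiplicative sample biases
        m = make_matrix(2.0 ** log2x, design)
        before = cv(m)[1]
        after = cv(loess_normalize(m, params))[1]
        assert after <= before
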