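"""MA transform, spread-curve fitting, MAID scores, and the k-of-n filter."""

import itertools

import numpy as np
import pandas as pd
import pytest

from maidflow import (
    DesignError,
    FilterResult,
    ScoreTable,
    compute_scores,
    filter_features,
    fit_maid_curve,
    ma_transform,
    maid_score,
    summarize_counts,
)
from maidflow.maid import MAPair
from maidflow.simulate import simulate_ma_cloud

from conftest import make_design, make_matrix

FLOOR = 0.004


def _pair(M, A, usable=None, fully=None):
    n = len(M)
    return MAPair(
        patient="P",
        comparison=("t", "b"),
        features=pd.Index([f"f{i}" for i in range(n)]),
        M=np.asarray(M, float),
        A=np.asarray(A, float),
        usable=np.ones(n, bool) if usable is None else np.asarray(usable, bool),
        fully_detected=None if fully is None else np.asarray(fully, bool),
    )


class TestMATransform:
    def test_identical_samples_give_zero_m(self):
        design = make_design(n_patients=1)
        m = make_matrix(np.array([[100.0, 100.0], [5.0, 5.0]]), design)
        pair = ma_transform(m, "Pat1", ("t48h", "baseline"), FLOOR)
        np.testing.assert_allclose(pair.M, 0.0)

    def test_fourfold_change_arithmetic(self):
        design = make_design(n_patients=1)
        m = make_matrix(np.array([[100.0, 400.0]]), design)
        pair = ma_transform(m, "Pat1", ("t48h", "baseline"), FLOOR)
        assert pair.M[0] == pytest.approx(2.0)
        assert pair.A[0] == pytest.approx(7.6439, abs=1e-4)

    def test_both_censored_is_unusable_with_zero_m(self):
        design = make_design(n_patients=1)
        m = make_matrix(
            np.array([[FLOOR, FLOOR]]),
            design,
            mask=np.array([[False, False]]),
        )
        pair = ma_transform(m, "Pat1", ("t48h", "baseline"), FLOOR)
        assert not pair.usable[0]
        assert pair.M[0] == 0.0

    def test_missing_sample_is_design_error(self):
        design = make_design(n_patients=1)
        m = make_matrix(np.array([[100.0, 200.0]]), design)
        with pytest.raises(DesignError, match="missing sample"):
            ma_transform(m, "Pat1", ("m1", "baseline"), FLOOR)


class TestFitMaidCurve:
    def test_homoscedastic_cloud_yields_flat_curve(self):
        rng = np.random.default_rng(21)
        sigma = 0.8
        pair = _pair(rng.normal(0, sigma, 5000), rng.uniform(0, 12, 5000))
        curve = fit_maid_curve(pair)
        grid = np.linspace(0.5, 11.5, 50)
        assert np.max(np.abs(np.asarray(curve(grid)) - sigma)) < 0.1 * sigma

    def test_planted_exponential_curve_recovered(self):
        pair = simulate_ma_cloud(5000, (2.0, 0.5, 0.1), a_range=(0.0, 12.0), seed=11)
        curve = fit_maid_curve(pair)
        grid = np.linspace(1.2, 10.8, 60)  # central 80% of the A-range
        true = 2.0 * np.exp(-0.5 * grid) + 0.1
        rel = np.abs(np.asarray(curve(grid)) - true) / true
        assert rel.max() < 0.15

    def test_ten_usable_features_fall_back_to_three_bins(self):
        rng = np.random.default_rng(2)
        pair = _pair(rng.normal(0, 1, 10), rng.uniform(0, 5, 10))
        curve = fit_maid_curve(pair, n_bins=20)
        assert len(curve.bin_centers) == 3

    def test_too_few_usable_features_is_an_error(self):
        rng = np.random.default_rng(2)
        pair = _pair(rng.normal(0, 1, 4), rng.uniform(0, 5, 4))
        with pytest.raises(Exception, match="usable"):
            fit_maid_curve(pair)

    def test_curve_is_positive_and_non_increasing(self):
        pair = simulate_ma_cloud(2000, (1.0, 0.3, 0.2), seed=3)
        curve = fit_maid_curve(pair)
        grid = np.linspace(-2, 14, 100)
        vals = np.asarray(curve(grid))
        assert (vals > 0).all()
        assert (np.diff(vals) <= 1e-12).all()


class TestMaidScore:
    def test_zero_m_scores_zero_and_ratio_form(self):
        pair = simulate_ma_cloud(200, (0.0, 0.0, 0.5), seed=4)
        pair.M[:] = 0.0
        pair.M[0] = 1.0
        curve = fit_maid_curve(pair)
        scores = maid_score(pair, curve)
        assert scores[0] == pytest.approx(1.0 / np.asarray(curve(pair.A[0])), rel=1e-9)
        np.testing.assert_allclose(scores[1:], 0.0)

    def test_antisymmetric_under_treated_baseline_swap(self):
        rng = np.random.default_rng(9)
        design = make_design(n_patients=1)
        m = make_matrix(2.0 ** rng.normal(4, 2, (300, 2)), design)
        fwd = ma_transform(m, "Pat1", ("t48h", "baseline"), FLOOR)
        rev = ma_transform(m, "Pat1", ("baseline", "t48h"), FLOOR)
        c_fwd = fit_maid_curve(fwd)
        c_rev = fit_maid_curve(rev)
        np.testing.assert_allclose(
            maid_score(fwd, c_fwd), -maid_score(rev, c_rev), rtol=1e-9
        )

    def test_unusable_features_score_zero(self):
        pair = _pair([3.0, 0.0], [5.0, 5.0], usable=[False, True])
        curve = fit_maid_curve(simulate_ma_cloud(500, (0.0, 0.0, 1.0), seed=5))
        assert maid_score(pair, curve)[0] == 0.0


def _table(score_rows: np.ndarray, comparisons=(("t48h", "baseline"),)) -> ScoreTable:
    """score_rows: (features, patients) per single comparison, or 3-d tensor."""
    arr = np.asarray(score_rows, float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return ScoreTable(
        features=pd.Index([f"f{i}" for i in range(arr.shape[0])]),
        patients=tuple(f"P{i}" for i in range(arr.shape[1])),
        comparisons=tuple(comparisons),
        scores=arr,
    )


class TestFilterFeatures:
    def test_four_of_six_above_cutoff_passes(self):
        table = _table([[2.5, 2.5, 2.5, 2.5, 0.0, 0.0]])
        res = filter_features(table, C=2.0, k=4)
        assert res.union_up == {"f0"} and not res.union_down

    def test_three_of_six_is_excluded(self):
        table = _table([[2.5, 2.5, 2.5, 0.0, 0.0, 0.0]])
        res = filter_features(table, C=2.0, k=4)
        assert not res.union_up and not res.union_down

    def test_all_zero_scores_give_empty_result(self):
        res = filter_features(_table(np.zeros((5, 6))), C=1.0, k=4)
        assert res.union_count == 0

    def test_exactly_at_cutoff_does_not_pass(self):
        res = filter_features(_table([[2.0] * 6]), C=2.0, k=4)
        assert res.union_count == 0  # strict inequality: score > C

    def test_monotone_in_cutoff_and_k(self):
        rng = np.random.default_rng(13)
        tensor = rng.normal(0, 1.5, (60, 6, 3))
        comps = (("a", "b"), ("c", "b"), ("d", "b"))
        table = _table(tensor, comparisons=comps)
        for c_lo, c_hi in [(0.5, 1.0), (1.0, 2.0)]:
            lo = filter_features(table, C=c_lo, k=3)
            hi = filter_features(table, C=c_hi, k=3)
            assert hi.union_up <= lo.union_up and hi.union_down <= lo.union_down
        for k_lo, k_hi in [(2, 3), (3, 5)]:
            lo = filter_features(table, C=0.8, k=k_lo)
            hi = filter_features(table, C=0.8, k=k_hi)
            assert hi.union_up <= lo.union_up and hi.union_down <= lo.union_down

    def test_agrees_with_exhaustive_triple_enumeration(self):
        rng = np.random.default_rng(17)
        tensor = rng.normal(0, 1.5, (20, 6, 3))
        comps = (("a", "b"), ("c", "b"), ("d", "b"))
        table = _table(tensor, comparisons=comps)
        C, k = 1.0, 4
        res = filter_features(table, C=C, k=k)
        # brute force over every (feature, comparison, direction) triple
        for fi in range(20):
            for ci, comp in enumerate(comps):
                n_up = sum(tensor[fi, pi, ci] > C for pi in range(6))
                n_dn = sum(tensor[fi, pi, ci] < -C for pi in range(6))
                assert (f"f{fi}" in res.per_comparison[comp][0]) == (n_up >= k)
                assert (f"f{fi}" in res.per_comparison[comp][1]) == (n_dn >= k)
        brute_up = {
            f"f{fi}"
            for fi in range(20)
            for ci in range(3)
            if sum(tensor[fi, pi, ci] > C for pi in range(6)) >= k
        }
        assert res.union_up == brute_up

    def test_patient_and_feature_order_do_not_matter(self):
        rng = np.random.default_rng(19)
        tensor = rng.normal(0, 1.5, (30, 6, 2))
        comps = (("a", "b"), ("c", "b"))
        table = _table(tensor, comparisons=comps)
        res = filter_features(table, C=1.0, k=3)
        perm_f = rng.permutation(30)
        perm_p = rng.permutation(6)
        shuffled = ScoreTable(
            features=table.features[perm_f],
            patients=tuple(np.asarray(table.patients)[perm_p]),
            comparisons=comps,
            scores=tensor[np.ix_(perm_f, perm_p, np.arange(2))],
        )
        res2 = filter_features(shuffled, C=1.0, k=3)
        assert res.union_up == res2.union_up and res.union_down == res2.union_down
        for comp in comps:
            assert res.per_comparison[comp] == res2.per_comparison[comp]

    def test_cross_direction_conflicts_are_flagged(self):
        tensor = np.zeros((1, 6, 2))
        tensor[0, :, 0] = 3.0
        tensor[0, :, 1] = -3.0
        table = _table(tensor, comparisons=(("a", "b"), ("c", "b")))
        res = filter_features(table, C=1.0, k=4)
        assert res.union_up == {"f0"} and res.union_down == {"f0"}
        assert res.conflicts == {"f0"}


class TestSummarizeCounts:
    def test_empty_result_is_all_zero(self):
        res = filter_features(_table(np.zeros((4, 6))), C=1.0, k=4)
        counts = summarize_counts(res)
        assert (counts[["up", "down", "total"]].to_numpy() == 0).all()

    def test_union_row_counts_distinct_features(self):
        res = FilterResult(
            per_comparison={
                ("a", "b"): ({"x", "y"}, set()),
                ("c", "b"): ({"y", "z"}, set()),
            },
            union_up={"x", "y", "z"},
            union_down=set(),
            conflicts=set(),
            k_required=4,
            n_patients=6,
            cutoff=1.0,
        )
        counts = summarize_counts(res)
        total = counts[counts.comparison == "Total"]
        assert int(total.up.iloc[0]) == 3 and int(total.total.iloc[0]) == 3


class TestColumnOrderInvariance:
    def test_shuffled_matrix_columns_give_identical_filter_result(self, small_cohort):
        (matrix, _), _ = small_cohort
        from maidflow import ct_to_linear

        lin = ct_to_linear(matrix)
        rng = np.random.default_rng(23)
        shuffled_cols = list(rng.permutation(lin.samples))
        shuffled = lin.with_values(
            lin.values[shuffled_cols], detection_mask=lin.detection_mask[shuffled_cols]
        )
        res1 = filter_features(compute_scores(lin, floor=FLOOR), C=1.0, k=4)
        res2 = filter_features(compute_scores(shuffled, floor=FLOOR), C=1.0, k=4)
        assert res1.union_up == res2.union_up
        assert res1.union_down == res2.union_down
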