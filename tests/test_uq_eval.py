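"""Outlier accuracy, classification rates, calibration — vs brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pesuq.uq_eval import (
    CalibrationCurve,
    ScoredTestSet,
    calibration_curve,
    classify_predictions,
    error_distribution_report,
    outlier_accuracy,
    outlier_grid,
    rates,
    threshold_sweep,
)


def _random_scored(rng, n=200, variance=True):
    return ScoredTestSet(
        indices=np.arange(n),
        squared_error=rng.uniform(0, 10, n) ** 2,
        uncertainty=rng.uniform(0, 5, n),
        uncertainty_is_variance=variance,
    )


def _brute_force_accuracy(scored, n_err, n_var):
    order_err = sorted(
        range(len(scored)),
        key=lambda i: (-scored.squared_error[i], i),
    )[:n_err]
    order_var = sorted(
        range(len(scored)),
        key=lambda i: (-scored.uncertainty[i], i),
    )[:n_var]
    return len(set(order_err) & set(order_var)) / min(n_err, n_var)


class TestOutlierAccuracy:
    def test_perfectly_aligned_rankings(self):
        v = np.arange(50.0)
        scored = ScoredTestSet(np.arange(50), v**2, v)
        assert outlier_accuracy(scored, 10, 10) == 1.0

    def test_anti_aligned_rankings(self):
        v = np.arange(50.0)
        scored = ScoredTestSet(np.arange(50), v**2, -v)
        assert outlier_accuracy(scored, 25, 25) == 0.0

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 120))
            scored = _random_scored(rng, n)
            n_err = int(rng.integers(1, n))
            n_var = int(rng.integers(1, n))
            assert outlier_accuracy(scored, n_err, n_var) == pytest.approx(
                _brute_force_accuracy(scored, n_err, n_var)
            )

    def test_invariant_under_monotone_transform(self, rng):
        scored = _random_scored(rng, 150)
        transformed = ScoredTestSet(
            scored.indices,
            scored.squared_error,
            np.exp(scored.uncertainty / 2.0) + 7.0,
        )
        for n_err, n_var in [(5, 20), (30, 30), (50, 10)]:
            assert outlier_accuracy(scored, n_err, n_var) == outlier_accuracy(
                transformed, n_err, n_var
            )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-100.0, 100.0),
    )
    def test_rank_statistic_property(self, seed, scale, shift):
        """Accuracy depends only on the ordering of the uncertainty scores:
        any positive affine transform leaves every cell unchanged."""
        gen = np.random.default_rng(seed)
        n = 40
        scored = ScoredTestSet(
            np.arange(n), gen.uniform(0, 4, n), gen.uniform(0, 2, n)
        )
        transformed = ScoredTestSet(
            scored.indices,
            scored.squared_error,
            scale * scored.uncertainty + shift,
        )
        assert outlier_accuracy(scored, 7, 15) == outlier_accuracy(
            transformed, 7, 15
        )

    def test_literal_normalization_option(self):
        v = np.arange(100.0)
        scored = ScoredTestSet(np.arange(100), v**2, v)
        # a perfect detector under the literal form scores n_err/n_var
        assert outlier_accuracy(
            scored, 5, 50, normalization="n_var"
        ) == pytest.approx(5 / 50)

    def test_bad_k_rejected(self, rng):
        scored = _random_scored(rng, 30)
        with pytest.raises(ValueError):
            outlier_accuracy(scored, 0, 10)
        with pytest.raises(ValueError):
            outlier_accuracy(scored, 10, 31)


class TestOutlierGrid:
    def test_perfect_ranking_gives_all_ones(self):
        v = np.arange(1200.0)
        scored = ScoredTestSet(np.arange(1200), v**2, v)
        grid = outlier_grid(scored)
        acc = grid.accuracy[np.isfinite(grid.accuracy)]
        assert np.allclose(acc, 1.0)

    def test_cells_match_fresh_calls(self, rng):
        scored = _random_scored(rng, 500)
        grid = outlier_grid(scored, [25, 50], [50, 100, 400])
        for i, ne in enumerate(grid.n_err_values):
            for j, nv in enumerate(grid.n_var_values):
                if ne <= nv:
                    assert grid.accuracy[i, j] == outlier_accuracy(
                        scored, ne, nv
                    )
                else:
                    assert np.isnan(grid.accuracy[i, j])

    def test_unsorted_lists_rejected(self, rng):
        with pytest.raises(ValueError):
            outlier_grid(_random_scored(rng, 100), [50, 25], [50])

    def test_long_format_frame(self, rng):
        grid = outlier_grid(_random_scored(rng, 200), [25], [25, 50])
        frame = grid.to_frame()
        assert set(frame.columns) == {"n_err", "n_var", "accuracy"}
        assert len(frame) == 2


class TestClassification:
    def test_all_above_both_thresholds(self):
        scored = ScoredTestSet(
            np.arange(4), np.full(4, 9.0), np.full(4, 5.0)
        )
        counts = classify_predictions(scored, 1.0, 1.0)
        assert counts.n_tp == 4 and counts.total == 4

    def test_errors_high_variance_low_all_fn(self):
        scored = ScoredTestSet(
            np.arange(4), np.full(4, 9.0), np.full(4, 0.1)
        )
        counts = classify_predictions(scored, 1.0, 1.0)
        assert counts.n_fn == 4

    def test_hand_built_eight_point_set(self):
        err = np.array([9.0, 9.0, 0.1, 0.1, 9.0, 0.1, 9.0, 0.1])
        var = np.array([5.0, 0.2, 5.0, 0.2, 5.0, 5.0, 0.2, 0.2])
        scored = ScoredTestSet(np.arange(8), err, var)
        counts = classify_predictions(scored, 1.0, 1.0)
        # manual tabulation: TP at 0,4; FP at 2,5; FN at 1,6; TN at 3,7
        assert (counts.n_tp, counts.n_fp, counts.n_tn, counts.n_fn) == (
            2, 2, 2, 2,
        )

    def test_equality_counts_as_negative_and_is_logged(self):
        scored = ScoredTestSet(np.arange(2), np.array([4.0, 9.0]),
                               np.array([2.0, 3.0]))
        counts = classify_predictions(scored, 4.0, 2.0)
        assert counts.n_tn + counts.n_fn >= 1
        assert counts.n_ties == 2

    def test_default_thresholds_are_means(self, rng):
        scored = _random_scored(rng, 50)
        counts = classify_predictions(scored)
        assert counts.epsilon_star == pytest.approx(
            scored.squared_error.mean()
        )
        assert counts.sigma_star == pytest.approx(scored.uncertainty.mean())


class TestRates:
    def test_forced_arithmetic(self):
        from pesuq.uq_eval import ConfusionCounts

        counts = ConfusionCounts(3, 0, 0, 1, 1.0, 1.0)
        r = rates(counts)
        assert r.r_tp == 0.75 and r.r_fn == 0.25

    def test_sensitivity_miss_rate_identity(self, rng):
        for _ in range(20):
            scored = _random_scored(rng, 60)
            r = rates(classify_predictions(scored))
            if not np.isnan(r.r_tp):
                assert r.r_tp + r.r_fn == pytest.approx(1.0)

    def test_undefined_ratio_flagged_not_raised(self):
        from pesuq.uq_eval import ConfusionCounts

        r = rates(ConfusionCounts(0, 0, 5, 0, 1.0, 1.0))
        assert np.isnan(r.p_tp) and "p_tp" in r.undefined

    def test_threshold_sweep_shape(self, rng):
        frame = threshold_sweep(_random_scored(rng, 100), n_points=5)
        assert len(frame) == 25
        assert {"r_tp", "p_tp", "r_fp", "r_fn"} <= set(frame.columns)


class TestCalibration:
    def test_chi_square_simulated_scores_are_calibrated(self, rng):
        # error^2 = variance * chi^2_1 -> per-bin RMSE tracks RMV
        n = 2000
        var = rng.uniform(0.5, 5.0, n)
        err2 = var * rng.chisquare(1, n)
        scored = ScoredTestSet(np.arange(n), err2, var)
        curve = calibration_curve(scored, n_bins=10)
        assert np.all(np.abs(curve.rmse / curve.rmv - 1.0) < 0.25)

    def test_constant_variance_single_rmv(self):
        scored = ScoredTestSet(
            np.arange(40), np.random.default_rng(0).uniform(0, 1, 40),
            np.full(40, 2.0),
        )
        curve = calibration_curve(scored, n_bins=4)
        assert np.allclose(curve.rmv, np.sqrt(2.0))

    def test_bins_partition_the_set(self, rng):
        scored = _random_scored(rng, 173)
        curve = calibration_curve(scored, n_bins=7)
        assert curve.counts.sum() == 173

    def test_nll_scores_rejected_with_explanation(self, rng):
        scored = _random_scored(rng, 50, variance=False)
        with pytest.raises(TypeError, match="NLL"):
            calibration_curve(scored, n_bins=5)


class TestReport:
    def test_degenerate_errors_single_bin(self):
        scored = ScoredTestSet(
            np.arange(10), np.full(10, 4.0), np.arange(10) + 1.0
        )
        report = error_distribution_report(scored)
        assert len(report["error_hist"]) == 1
        assert report["error_hist"]["count"].iloc[0] == 10

    def test_summary_matches_direct_minmax(self, rng):
        scored = _random_scored(rng, 80)
        report = error_distribution_report(scored)
        row = report["summary"].set_index("quantity")
        assert row.loc["squared_error", "min"] == scored.squared_error.min()
        assert row.loc["uncertainty", "max"] == scored.uncertainty.max()

    def test_top_uncertainty_subset_flagged(self, rng):
        scored = _random_scored(rng, 300)
        report = error_distribution_report(scored, n_flagged=50)
        res = report["residuals"]
        assert res["top_uncertainty"].sum() == 50
        flagged_min = res.loc[res.top_uncertainty, "uncertainty"].min()
        unflagged_max = res.loc[~res.top_uncertainty, "uncertainty"].max()
        assert flagged_min >= unflagged_max
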