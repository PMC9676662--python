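"""PLS-DA model machinery: NIPALS, CV, thresholds, metrics, outlier screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedhsi import (SpectraTable, classify, evaluate, fit_pls,
                     hotelling_screen, predict_scores, select_lv,
                     shift_threshold, split_calibration_validation)
from seedhsi.plsda import coefficient_peaks
from seedhsi.synth import default_grid


class TestHotelling:
    def test_row_at_column_mean_not_flagged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 6))
        X[0] = X.mean(axis=0)  # recompute below: make row 0 the mean exactly
        X[0] = (X.sum(axis=0) - X[0]) / (X.shape[0] - 1)
        X[0] = X.mean(axis=0)  # fixed point after one more assignment
        res = hotelling_screen(X)
        assert res.t_squared[0] < 1e-10 * res.limit or not res.flags[0]

    def test_flag_rate_matches_f_quantile(self):
        """~1.1% of bivariate-normal rows exceed the 98.9% ellipse."""
        rng = np.random.default_rng(1)
        fractions = [hotelling_screen(rng.normal(size=(1000, 2)),
                                      0.989).flagged_fraction
                     for _ in range(30)]
        assert 0.008 < np.mean(fractions) < 0.014

    def test_confidence_out_of_range_raises(self):
        with pytest.raises(ValueError, match="confidence"):
            hotelling_screen(np.zeros((10, 3)) + np.eye(10, 3), 1.2)

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 8))
        X[17] += 50.0
        assert hotelling_screen(X).flags[17]


def _table(n_seeds_per_class, variety="V2"):
    """Balanced double-sided table: 2 rows (sides) per seed."""
    grid = default_grid(16)
    rows, meta = [], []
    k = 0
    for lab in (0, 1):
        for _ in range(n_seeds_per_class):
            for side in ("A", "B"):
                rows.append(np.linspace(0.2, 0.8, 16) + 0.01 * lab)
                meta.append({"sample_id": f"{variety}_{k:04d}",
                             "variety": variety, "side": side, "label": lab,
                             "split": "unassigned"})
            k += 1
    return SpectraTable(np.array(rows), grid, pd.DataFrame(meta))


class TestSplit:
    def test_two_thirds_of_612_gives_408_204(self):
        table = _table(153)  # 153 seeds x 2 sides x 2 classes = 612 rows
        out = split_calibration_validation(table, 2 / 3, rng=0)
        counts = out.meta["split"].value_counts()
        assert counts["calibration"] == 408
        assert counts["validation"] == 204

    def test_full_fraction_empties_validation(self):
        out = split_calibration_validation(_table(6), 1.0, rng=0)
        assert (out.meta["split"] == "calibration").all()

    def test_sides_of_one_seed_never_straddle_splits(self):
        out = split_calibration_validation(_table(20), 2 / 3, rng=1)
        per_seed = out.meta.groupby("sample_id")["split"].nunique()
        assert (per_seed == 1).all()

    def test_unbalanced_input_raises_with_advice(self):
        table = _table(10)
        table = table.subset(np.arange(len(table)) >= 4)  # drop 2 nonviable
        with pytest.raises(ValueError, match="downsample"):
            split_calibration_validation(table, 2 / 3, rng=0)


class TestFit:
    def test_exact_fit_limit(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        beta = rng.normal(size=5)
        y = X @ beta + 2.0
        model = fit_pls(X, y, n_lv=5)
        np.testing.assert_allclose(predict_scores(model, X), y, atol=1e-8)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 25))
        y = rng.normal(size=40)
        model = fit_pls(X, y, n_lv=25)
        b_ols = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(model.coef, b_ols, atol=1e-6)

    def test_matches_reference_pls_implementation(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(5)
        for n_lv in (1, 4, 10):
            X = rng.normal(size=(40, 25))
            y = rng.normal(size=40)
            model = fit_pls(X, y, n_lv)
            ref = PLSRegression(n_components=n_lv, scale=False).fit(X, y)
            np.testing.assert_allclose(predict_scores(model, X),
                                       ref.predict(X).ravel(), atol=1e-6)

    def test_explained_x_variance_positive_and_bounded(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        model = fit_pls(X, y, 8)
        assert np.all(model.x_variance > 0)
        assert model.x_variance.sum() <= 1 + 1e-12

    def test_zero_variance_x_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_pls(np.ones((10, 4)), np.arange(10.0), 2)

    def test_univariate_separable_single_lv(self):
        X = np.arange(20, dtype=float)[:, None]
        y = (X[:, 0] > 9.5).astype(float)
        model = fit_pls(X, y, 1)
        pred = classify(predict_scores(model, X), 0.5)
        np.testing.assert_array_equal(pred, y.astype(int))


class TestPredict:
    def test_training_mean_scores_training_mean(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 9))
        y = rng.random(25)
        model = fit_pls(X, y, 3)
        score = predict_scores(model, X.mean(axis=0)[None, :])
        assert score[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_duplicate_rows_identical_scores(self):
        rng = np.random.default_rng(8)
        model = fit_pls(rng.normal(size=(20, 6)), rng.random(20), 2)
        row = rng.normal(size=6)
        scores = predict_scores(model, np.vstack([row, row]))
        assert scores[0] == scores[1]

    def test_matches_explicit_dot_product(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 6))
        model = fit_pls(X, rng.random(20), 3)
        Xn = rng.normal(size=(5, 6))
        expected = [float((x - model.x_mean) @ model.coef + model.y_mean)
                    for x in Xn]
        np.testing.assert_allclose(predict_scores(model, Xn), expected,
                                   atol=1e-12)

    def test_band_mismatch_raises(self):
        rng = np.random.default_rng(10)
        model = fit_pls(rng.normal(size=(20, 6)), rng.random(20), 2)
        with pytest.raises(ValueError, match="band mismatch"):
            predict_scores(model, np.zeros((3, 7)))


class TestSelectLV:
    def test_error_curve_has_max_lv_entries(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 10))
        y = rng.integers(0, 2, 40).astype(float)
        best, curve = select_lv(X, y, max_lv=6, k_folds=5, rng=0)
        assert curve.shape == (6,)
        assert 1 <= best <= 6

    def test_separable_data_selects_first_zero_error(self):
        rng = np.random.default_rng(12)
        y = np.repeat([0.0, 1.0], 20)
        X = rng.normal(size=(40, 8)) * 0.01
        X[:, 0] += y * 10  # one direction separates perfectly
        best, curve = select_lv(X, y, max_lv=5, k_folds=5, rng=0)
        assert curve[best - 1] == 0.0
        assert np.all(curve[:best - 1] > 0.0)  # earliest zero wins ties

    def test_more_folds_than_rows_raises(self):
        with pytest.raises(ValueError, match="folds"):
            select_lv(np.zeros((5, 3)), np.zeros(5), 2, k_folds=6)


class TestClassify:
    @pytest.mark.parametrize("score,t,expected", [
        (0.6, 0.5, 1),
        (0.52, 0.53, 0),
        (0.5, 0.5, 0),     # tie goes nonviable
    ])
    def test_threshold_rule(self, score, t, expected):
        assert classify(np.array([score]), t)[0] == expected

    def test_invalid_threshold_raises(self):
        with pytest.raises(ValueError):
            classify(np.array([0.5]), 1.5)


class TestShiftThreshold:
    def test_separated_scores_keep_half(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = shift_threshold(scores, labels, 1.0)
        assert res.threshold == 0.5 and res.reached

    def test_borderline_nonviable_forces_one_step(self):
        scores = np.array([0.1, 0.2, 0.51, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = shift_threshold(scores, labels, 1.0)
        assert res.threshold == pytest.approx(0.52)

    def test_unreachable_target_returns_grid_max_flagged(self):
        scores = np.array([0.999, 0.999])
        labels = np.array([0, 1])
        res = shift_threshold(scores, labels, 1.0)
        assert res.threshold == pytest.approx(0.99) and not res.reached

    def test_invalid_target_raises(self):
        with pytest.raises(ValueError, match="purity"):
            shift_threshold(np.array([0.5]), np.array([1]), 0.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.5, 1.0), st.floats(0.5, 1.0))
    def test_threshold_monotone_in_purity_target(self, seed, t1, t2):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 30)
        scores = np.clip(rng.normal(0.3 + 0.4 * labels, 0.2), 0, 1)
        lo, hi = sorted((t1, t2))
        assert (shift_threshold(scores, labels, lo).threshold
                <= shift_threshold(scores, labels, hi).threshold)

    def test_raising_threshold_never_adds_false_viables(self):
        rng = np.random.default_rng(13)
        labels = rng.integers(0, 2, 200)
        scores = np.clip(rng.normal(0.3 + 0.4 * labels, 0.25), 0, 1)
        fv = [np.sum((scores > t) & (labels == 0))
              for t in np.arange(0.5, 1.0, 0.01)]
        assert all(a >= b for a, b in zip(fv, fv[1:]))


class TestEvaluate:
    def test_perfect_labels(self):
        truth = np.array([0, 1, 1, 0, 1])
        cm = evaluate(truth, truth)
        assert cm.acc_viable == 1.0 and cm.fp == cm.fn == 0

    def test_all_predicted_nonviable_gives_zero_acc_v(self):
        truth = np.array([0, 1, 1, 0])
        cm = evaluate(np.zeros(4, dtype=int), truth)
        assert cm.acc_viable == 0.0

    def test_matches_bruteforce_count(self):
        rng = np.random.default_rng(14)
        pred = rng.integers(0, 2, 200)
        truth = rng.integers(0, 2, 200)
        cm = evaluate(pred, truth)
        counts = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for p, t in zip(pred, truth):
            key = ("t" if p == t else "f") + ("p" if p == 1 else "n")
            counts[key] += 1
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (
            counts["tp"], counts["fp"], counts["tn"], counts["fn"])
        assert cm.accuracy == pytest.approx((counts["tp"] + counts["tn"]) / 200)

    def test_nonbinary_label_raises(self):
        with pytest.raises(ValueError, match="0 or 1"):
            evaluate(np.array([0, 2]), np.array([0, 1]))


def test_coefficient_peaks_finds_planted_bands():
    wl = np.linspace(900, 1700, 200)
    b = np.zeros(200)
    for c, h in ((1415, 1.0), (1475, -0.8), (1605, 0.9)):
        b += h * np.exp(-0.5 * ((wl - c) / 10) ** 2)
    from seedhsi.plsda import PLSDAModel
    model = PLSDAModel(1, b, np.zeros(200), 0.5, b[:, None], b[:, None],
                       np.ones(1))
    peaks = sorted(coefficient_peaks(model, wl, 3))
    for got, want in zip(peaks, (1415, 1475, 1605)):
        assert abs(got - want) < 5
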