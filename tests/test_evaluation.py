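"""Metrics against brute-force oracles; comparison, ablation, attribution."""

import numpy as np
import pandas as pd
import pytest

from immunonet.evaluation import (
    auc_pr,
    auc_roc,
    confusion_matrix,
    evaluate,
    f1_score_pct,
    make_baseline,
    multi_run_compare,
    permutation_importance,
    precision_recall_f1,
    run_ablation,
)
from immunonet.preprocess import FeatureMatrix
from immunonet.training import Hyperparams


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and independent)
# ---------------------------------------------------------------------------

def brute_prf(y_true, y_pred, K):
    prec, rec, f1 = [], [], []
    for k in range(K):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == k and p == k)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != k and p == k)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == k and p != k)
        P = tp / (tp + fp) if tp + fp else 0.0
        R = tp / (tp + fn) if tp + fn else 0.0
        prec.append(100 * P)
        rec.append(100 * R)
        f1.append(200 * P * R / (P + R) if P + R else 0.0)
    return prec, rec, f1


def brute_auc_roc(pos, scores):
    """Concordant-pair fraction, half credit for ties."""
    pairs = concordant = 0.0
    for i, (pi, si) in enumerate(zip(pos, scores)):
        if not pi:
            continue
        for pj, sj in zip(pos, scores):
            if pj:
                continue
            pairs += 1
            if si > sj:
                concordant += 1
            elif si == sj:
                concordant += 0.5
    return concordant / pairs


def brute_auc_pr(pos, scores):
    """Sum of precision × recall increments over descending thresholds."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    pos = np.asarray(pos)[order]
    scores = np.asarray(scores)[order]
    total_pos = pos.sum()
    area = prev_recall = 0.0
    tp = fp = 0
    i = 0
    while i < len(pos):
        j = i
        while j < len(pos) and scores[j] == scores[i]:
            tp += pos[j]
            fp += not pos[j]
            j += 1
        recall = tp / total_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


# ---------------------------------------------------------------------------

class TestConfusionMatrix:
    def test_hand_tally(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 2]])

    def test_perfect_predictions_are_diagonal(self):
        y = [0, 1, 2, 2, 1, 0, 0]
        cm = confusion_matrix(y, y, 3)
        np.testing.assert_array_equal(cm, np.diag([3, 2, 2]))

    def test_total_count_conserved(self):
        rng = np.random.default_rng(0)
        y_true, y_pred = rng.integers(0, 4, 57), rng.integers(0, 4, 57)
        assert confusion_matrix(y_true, y_pred, 4).sum() == 57

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], 2)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 5], [0, 1], 2)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "precision, recall, printed_f1",
        [
            (97.5, 98.4, 97.9),   # strongest classifier row
            (91.0, 93.0, 92.0),   # kernel-SVM comparator row
            (91.3, 93.5, 92.4),   # convolution-only ablation row
        ],
    )
    def test_harmonic_mean_reproduces_printed_table_cells(
        self, precision, recall, printed_f1
    ):
        assert round(f1_score_pct(precision, recall), 1) == printed_f1

    def test_f1_equals_precision_when_equal_to_recall(self):
        assert f1_score_pct(88.8, 88.8) == pytest.approx(88.8)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            cm = rng.integers(0, 20, size=(3, 3))
            per = precision_recall_f1(cm, averaging="per_class")
            for P, R, F in zip(per["precision"], per["recall"], per["f1"]):
                assert min(P, R) - 1e-9 <= F <= max(P, R) + 1e-9

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            K = rng.integers(2, 5)
            n = rng.integers(5, 50)
            y_true = rng.integers(0, K, n)
            y_pred = rng.integers(0, K, n)
            cm = confusion_matrix(y_true, y_pred, K)
            per = precision_recall_f1(cm, averaging="per_class")
            bp, br, bf = brute_prf(y_true, y_pred, K)
            np.testing.assert_allclose(per["precision"], bp, atol=1e-9)
            np.testing.assert_allclose(per["recall"], br, atol=1e-9)
            np.testing.assert_allclose(per["f1"], bf, atol=1e-9)
            macro = precision_recall_f1(cm, averaging="macro")
            assert macro["f1"] == pytest.approx(np.mean(bf))

    def test_weighted_averaging_uses_support(self):
        cm = np.array([[8, 2], [0, 0]])
        w = precision_recall_f1(cm, averaging="weighted")
        per = precision_recall_f1(cm, averaging="per_class")
        assert w["recall"] == pytest.approx(per["recall"][0])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(np.zeros((0, 0)))


class TestAucRoc:
    def test_perfect_separation_is_one(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        assert auc_roc(scores, [0, 0, 1, 1]) == 1.0

    def test_constant_scores_are_half(self):
        scores = np.full((6, 2), 0.5)
        assert auc_roc(scores, [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(4, 20)
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # ties likely
            scores = np.column_stack([1 - s, s])
            expected = (brute_auc_roc(y == 0, 1 - s) + brute_auc_roc(y == 1, s)) / 2
            assert auc_roc(scores, y) == pytest.approx(expected, abs=1e-12)

    def test_label_flip_antisymmetry_without_ties(self):
        rng = np.random.default_rng(4)
        s = rng.permutation(np.linspace(0.05, 0.95, 10))
        y = rng.integers(0, 2, 10)
        if len(set(y)) < 2:
            y[0], y[1] = 0, 1
        scores = np.column_stack([1 - s, s])
        a = auc_roc(scores, y)
        b = auc_roc(scores, 1 - y)
        assert a + b == pytest.approx(1.0)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            auc_roc(np.random.rand(5, 2), [1, 1, 1, 1, 1])


class TestAucPr:
    def test_perfect_separation_is_one(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        assert auc_pr(scores, [0, 0, 1, 1]) == 1.0

    def test_constant_scores_equal_prevalence(self):
        y = np.array([1, 0, 0, 1, 0, 0, 0, 0])
        scores = np.full((8, 2), 0.5)
        per_class = [1 - y.mean(), y.mean()]
        assert auc_pr(scores, y) == pytest.approx(np.mean(per_class))

    def test_matches_threshold_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(4, 20)
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            s = rng.choice([0.2, 0.4, 0.6, 0.8], size=n)
            scores = np.column_stack([1 - s, s])
            expected = (brute_auc_pr(y == 0, 1 - s) + brute_auc_pr(y == 1, s)) / 2
            assert auc_pr(scores, y) == pytest.approx(expected, abs=1e-12)


class TestMultiRunCompare:
    def test_identical_runs_zero_ci_p_one(self):
        acc = {"ref": [95.0] * 5, "other": [95.0] * 5}
        rep = multi_run_compare(acc, reference="ref")
        row = rep.table.set_index("model").loc["other"]
        assert row["ci95"] == 0.0
        assert row["p_value"] == 1.0 and not row["degenerate"]

    def test_constant_nonzero_difference_flagged_degenerate(self):
        acc = {"ref": [96.0] * 5, "other": [95.0] * 5}
        rep = multi_run_compare(acc, reference="ref")
        row = rep.table.set_index("model").loc["other"]
        assert row["p_value"] == 0.0 and row["degenerate"]

    def test_paired_t_statistic_matches_hand_formula(self):
        from scipy import stats

        ref = np.array([96.0, 95.5, 96.5, 95.8, 96.2])
        diffs = np.array([2.0, 1.5, 2.5, 1.8, 2.2])
        acc = {"ref": ref.tolist(), "other": (ref - diffs).tolist()}
        rep = multi_run_compare(acc, reference="ref")
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        expected_p = 2 * stats.t.sf(abs(t), df=4)
        row = rep.table.set_index("model").loc["other"]
        assert row["p_value"] == pytest.approx(expected_p, rel=1e-9)
        assert row["significant"]

    def test_ci_halfwidth_matches_t_formula(self):
        from scipy import stats

        acc = {"ref": [96.0, 95.0, 97.0, 94.5, 96.5], "o": [90.0] * 5}
        rep = multi_run_compare(acc, reference="ref")
        x = np.array(acc["ref"])
        expected = stats.t.ppf(0.975, 4) * x.std(ddof=1) / np.sqrt(5)
        row = rep.table.set_index("model").loc["ref"]
        assert row["ci95"] == pytest.approx(expected)
        assert row["p_value"] is None or np.isnan(row["p_value"])

    def test_reference_must_exist_and_runs_must_align(self):
        with pytest.raises(ValueError):
            multi_run_compare({"a": [1, 2]}, reference="b")
        with pytest.raises(ValueError):
            multi_run_compare({"a": [1, 2], "b": [1.0]}, reference="a")
        with pytest.raises(ValueError):
            multi_run_compare({"a": [1.0], "b": [1.0]}, reference="a")

    def test_fixed_inputs_give_identical_reports(self):
        acc = {"ref": [96.0, 95.2, 96.8], "m": [94.0, 93.8, 94.4]}
        a = multi_run_compare(acc, reference="ref")
        b = multi_run_compare(acc, reference="ref")
        pd.testing.assert_frame_equal(a.table, b.table)


class TestEvaluate:
    def test_sklearn_estimator_full_report(self, prepared_small):
        fm_train, _, fm_test, _ = prepared_small
        est = make_baseline("lr", 0)
        est.fit(fm_train.X, fm_train.y)
        rep = evaluate(est, fm_test)
        assert 0.0 <= rep.accuracy <= 100.0
        assert rep.auc_roc is not None and 0.0 <= rep.auc_roc <= 1.0
        assert rep.auc_pr is not None and 0.0 <= rep.auc_pr <= 1.0
        assert rep.confusion.sum() == len(fm_test.y)
        # the harmonic-mean bound holds class by class (not for macro means)
        for _, row in rep.per_class.iterrows():
            assert min(row.precision, row.recall) - 1e-9 <= row.f1
            assert row.f1 <= max(row.precision, row.recall) + 1e-9

    def test_bare_callable_omits_aucs(self, prepared_small):
        _, _, fm_test, _ = prepared_small
        rep = evaluate(lambda X: np.zeros(len(X), dtype=int), fm_test)
        assert rep.auc_roc is None


class TestRunAblation:
    def test_six_variant_table_internally_consistent(self, prepared_small):
        fm_train, fm_val, fm_test, _ = prepared_small
        hp = Hyperparams(epochs=2, patience=5, seed=0)
        report = run_ablation(
            (fm_train, fm_val, fm_test), hp, seeds=[0],
            channels=(2, 3), lstm_hidden=4, feat_dim=4, n_segments=3,
            mlp_hidden=(8,),
        )
        assert not report.failures
        assert len(report.table) == 6
        assert set(report.table.variant) == {
            "full", "cnn_only", "cnn_lstm", "cnn_topology", "lstm_only", "mlp_only",
        }
        for _, row in report.table.iterrows():
            assert row["f1"] == pytest.approx(
                f1_score_pct(row["precision"], row["recall"]), abs=1e-9
            )
        assert len(report.per_seed) == 6


class TestPermutationImportance:
    @staticmethod
    def _matrix(n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 3))
        y = (X[:, 1] > 0.5).astype(int)
        groups = {"a": slice(0, 1), "b": slice(1, 2), "c": slice(2, 3)}
        return FeatureMatrix(X=X, y=y, feature_names=["a", "b", "c"],
                             class_names=["neg", "pos"], groups=groups)

    def test_ignored_features_have_exactly_zero_importance(self):
        fm = self._matrix()
        predict = lambda X: (X[:, 1] > 0.5).astype(int)  # noqa: E731
        rep = permutation_importance(predict, fm, n_repeats=3, seed=0)
        tab = rep.table.set_index("feature")
        assert tab.loc["a", "importance"] == 0.0
        assert tab.loc["c", "importance"] == 0.0
        assert tab.loc["b", "importance"] > 0.3

    def test_informative_feature_ranks_first(self):
        fm = self._matrix(seed=3)
        predict = lambda X: (X[:, 1] > 0.5).astype(int)  # noqa: E731
        rep = permutation_importance(predict, fm, n_repeats=5, seed=1)
        assert rep.table.iloc[0]["feature"] == "b"

    def test_reproducible_under_fixed_seed(self):
        fm = self._matrix(seed=5)
        predict = lambda X: (X[:, 1] > 0.5).astype(int)  # noqa: E731
        a = permutation_importance(predict, fm, n_repeats=4, seed=9)
        b = permutation_importance(predict, fm, n_repeats=4, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_attribution_hook_receives_predictor(self):
        fm = self._matrix()
        predict = lambda X: (X[:, 1] > 0.5).astype(int)  # noqa: E731
        rep = permutation_importance(
            predict, fm, n_repeats=2, seed=0,
            attribution_hook=lambda fn, data: {"n": len(data.y)},
        )
        assert rep.hook_result == {"n": len(fm.y)}

    def test_single_row_rejected(self):
        fm = self._matrix()
        import dataclasses

        tiny = dataclasses.replace(fm, X=fm.X[:1], y=fm.y[:1])
        with pytest.raises(ValueError):
            permutation_importance(lambda X: np.zeros(len(X)), tiny)
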