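"""Evaluation metrics: per-class PRF, balanced accuracy, OvR AUC, aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from echorobust.metrics import (
    aggregate_sequences,
    auc_ovr,
    auc_ovr_arrays,
    balanced_accuracy,
    compute_report,
    make_table,
    round_half_up,
)
from tests.conftest import table_from_predictions

CLASSES = ["A2C", "A3C", "A4C", "A5C"]


def _table_with_recalls(recall_fractions):
    """Table whose per-class recalls are exactly the given (hits, support)."""
    y_true, y_pred = [], []
    for cls, (hits, support) in zip(CLASSES, recall_fractions):
        wrong = [c for c in CLASSES if c != cls][0]
        y_true += [cls] * support
        y_pred += [cls] * hits + [wrong] * (support - hits)
    return table_from_predictions(y_true, y_pred, CLASSES)


class TestBalancedAccuracy:
    def test_mean_of_reference_recall_rows(self):
        # recalls 0.760 / 0.850 / 0.856 / 1.000 -> 0.8665, printed as 0.867
        table = _table_with_recalls([(19, 25), (17, 20), (107, 125), (10, 10)])
        ba = balanced_accuracy(table)
        assert ba == pytest.approx(0.8665, abs=1e-12)
        assert round_half_up(ba, 3) == 0.867

    def test_mean_of_second_reference_recall_rows(self):
        # recalls 0.870 / 0.775 / 0.898 / 0.700 -> 0.811 (rounds from 0.81075)
        table = _table_with_recalls([(87, 100), (31, 40), (449, 500), (7, 10)])
        assert round_half_up(balanced_accuracy(table), 3) == 0.811

    def test_constant_predictor_scores_one_over_k(self):
        table = table_from_predictions(
            CLASSES * 5, ["A4C"] * 20, CLASSES
        )
        assert balanced_accuracy(table) == pytest.approx(0.25)

    def test_absent_classes_are_dropped_not_zeroed(self):
        table = table_from_predictions(
            ["A2C", "A2C", "A3C"], ["A2C", "A2C", "A3C"], CLASSES
        )
        assert balanced_accuracy(table) == pytest.approx(1.0)


class TestClassificationReport:
    def test_f1_from_reference_precision_recall_pair(self):
        # precision 0.741 (20/27), recall 1.000 -> F1 0.851
        y_true = ["A5C"] * 20 + ["A4C"] * 7 + ["A2C"] * 10
        y_pred = ["A5C"] * 27 + ["A2C"] * 10
        report = compute_report(table_from_predictions(y_true, y_pred, CLASSES))
        row = report.per_class.loc["A5C"]
        assert round_half_up(row["precision"], 3) == 0.741
        assert row["recall"] == 1.0
        assert round_half_up(row["f1"], 3) == 0.851

    def test_perfect_predictions_score_one_everywhere(self):
        y = CLASSES * 3
        report = compute_report(table_from_predictions(y, y, CLASSES))
        assert report.accuracy == 1.0
        assert report.balanced_accuracy == 1.0
        assert report.macro_f1 == 1.0

    def test_three_class_confusion_matrix_arithmetic(self):
        # confusion [[2,1,0],[0,3,0],[1,0,1]] -> recalls (2/3, 1, 1/2)
        classes = ["a", "b", "c"]
        y_true = ["a"] * 3 + ["b"] * 3 + ["c"] * 2
        y_pred = ["a", "a", "b", "b", "b", "b", "a", "c"]
        report = compute_report(table_from_predictions(y_true, y_pred, classes))
        np.testing.assert_array_equal(
            report.confusion.to_numpy(), [[2, 1, 0], [0, 3, 0], [1, 0, 1]]
        )
        assert report.balanced_accuracy == pytest.approx((2 / 3 + 1 + 0.5) / 3)
        assert round_half_up(report.balanced_accuracy, 3) == 0.722

    def test_f1_defined_as_zero_when_degenerate(self):
        y_true = ["a", "a", "b", "b"]
        y_pred = ["b", "b", "a", "a"]
        report = compute_report(table_from_predictions(y_true, y_pred, ["a", "b"]))
        assert (report.per_class["f1"] == 0.0).all()

    def test_supports_sum_to_table_size(self):
        table = _table_with_recalls([(3, 5), (2, 4), (6, 6), (1, 2)])
        report = compute_report(table)
        assert report.per_class["support"].sum() == len(table)

    def test_macro_metrics_invariant_to_relabeling(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(CLASSES, size=60).tolist()
        y_pred = rng.choice(CLASSES, size=60).tolist()
        r1 = compute_report(table_from_predictions(y_true, y_pred, CLASSES))
        swap = {"A2C": "A5C", "A5C": "A2C", "A3C": "A3C", "A4C": "A4C"}
        r2 = compute_report(
            table_from_predictions([swap[y] for y in y_true],
                                   [swap[y] for y in y_pred], CLASSES)
        )
        assert r1.macro_f1 == pytest.approx(r2.macro_f1)
        assert r1.balanced_accuracy == pytest.approx(r2.balanced_accuracy)

    def test_empty_table_rejected(self):
        table = table_from_predictions(["a"], ["a"], ["a", "b"]).iloc[:0]
        with pytest.raises(ValueError):
            compute_report(table)


def _brute_force_auc(y, scores, positive):
    pos = scores[y == positive]
    neg = scores[y != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAucOvr:
    def test_perfect_separation_gives_one(self):
        y_true = ["a"] * 3 + ["b"] * 3
        proba = np.array([[0.9, 0.1]] * 3 + [[0.1, 0.9]] * 3)
        table = make_table([f"f{i}" for i in range(6)], [f"s{i}" for i in range(6)],
                           y_true, proba, ["a", "b"])
        per_class, macro = auc_ovr(table)
        assert per_class == {"a": 1.0, "b": 1.0}
        assert macro == 1.0

    def test_constant_scores_give_half_by_midranks(self):
        y_true = ["a", "a", "b", "b"]
        proba = np.full((4, 2), 0.5)
        table = make_table(list("0123"), list("0123"), y_true, proba, ["a", "b"])
        _, macro = auc_ovr(table)
        assert macro == pytest.approx(0.5)

    def test_hand_computed_pair_counting_example(self):
        # labels (+,+,-,-) with scores (0.9, 0.4, 0.6, 0.1) -> 3 of 4 pairs won
        y = np.array([0, 0, 1, 1])
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        proba = np.column_stack([scores, 1 - scores])
        assert auc_ovr_arrays(y, proba)[0] == pytest.approx(0.75)

    def test_rank_statistic_matches_brute_force_on_small_tables(self):
        # exhaustive oracle: all random tables with <= 12 rows, with ties
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(3, 13)
            k = rng.integers(2, 5)
            y = rng.integers(0, k, size=n)
            if len(np.unique(y)) < 2:
                continue
            proba = rng.integers(0, 4, size=(n, k)) / 3.0  # coarse grid forces ties
            aucs = auc_ovr_arrays(y, proba)
            for cls in range(k):
                if (y == cls).all() or (y != cls).all():
                    assert np.isnan(aucs[cls])
                    continue
                assert aucs[cls] == pytest.approx(
                    _brute_force_auc(y, proba[:, cls], cls)
                )

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        y = rng.integers(0, 4, size=200)
        proba = rng.dirichlet(np.ones(4), size=200)
        ours = auc_ovr_arrays(y, proba)
        for k in range(4):
            ref = roc_auc_score((y == k).astype(int), proba[:, k])
            assert ours[k] == pytest.approx(ref)


class TestSequenceAggregation:
    def test_uniform_sequence_keeps_its_vector(self):
        proba = np.tile([0.7, 0.2, 0.1], (3, 1))
        table = make_table(["f0", "f1", "f2"], ["s0"] * 3, ["a"] * 3, proba,
                           ["a", "b", "c"])
        agg = aggregate_sequences(table)
        assert len(agg) == 1
        np.testing.assert_allclose(agg[["p_a", "p_b", "p_c"]].iloc[0], [0.7, 0.2, 0.1])

    def test_mean_probability_decides_label(self):
        proba = np.array([[0.6, 0.4], [0.2, 0.8]])
        table = make_table(["f0", "f1"], ["s0", "s0"], ["b", "b"], proba, ["a", "b"])
        agg = aggregate_sequences(table)
        np.testing.assert_allclose(agg[["p_a", "p_b"]].iloc[0], [0.4, 0.6])
        assert agg["predicted_label"].iloc[0] == "b"

    def test_tie_breaks_to_lowest_class_index(self):
        proba = np.array([[0.6, 0.4], [0.4, 0.6]])
        table = make_table(["f0", "f1"], ["s0", "s0"], ["a", "a"], proba, ["a", "b"])
        assert aggregate_sequences(table)["predicted_label"].iloc[0] == "a"

    def test_invariant_to_frame_order_and_duplication(self):
        rng = np.random.default_rng(1)
        proba = rng.dirichlet(np.ones(3), size=8)
        seqs = ["s0"] * 4 + ["s1"] * 4
        table = make_table([f"f{i}" for i in range(8)], seqs, ["a"] * 8, proba,
                           ["a", "b", "c"])
        shuffled = table.sample(frac=1, random_state=0)
        doubled = pd.concat([table, table.assign(frame_id=table.frame_id + "x")])
        base = aggregate_sequences(table)
        for variant in (shuffled, doubled):
            out = aggregate_sequences(variant)
            pd.testing.assert_frame_equal(
                base.reset_index(drop=True), out.reset_index(drop=True)
            )

    def test_inconsistent_sequence_labels_rejected(self):
        proba = np.array([[0.6, 0.4], [0.4, 0.6]])
        table = make_table(["f0", "f1"], ["s0", "s0"], ["a", "b"], proba, ["a", "b"])
        with pytest.raises(ValueError):
            aggregate_sequences(table)


class TestMakeTable:
    def test_argmax_ties_resolved_to_lowest_index(self):
        proba = np.array([[0.5, 0.5], [0.25, 0.75]])
        table = make_table(["f0", "f1"], ["s0", "s1"], ["a", "b"], proba, ["a", "b"])
        assert table["predicted_label"].tolist() == ["a", "b"]

    def test_unnormalized_probabilities_rejected(self):
        with pytest.raises(ValueError):
            make_table(["f0"], ["s0"], ["a"], np.array([[0.5, 0.2]]), ["a", "b"])
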