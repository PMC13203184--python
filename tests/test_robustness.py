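"""Degradation curves, failure-case filtering, learning curves."""

import numpy as np
import pandas as pd
import pytest

from echorobust.bootstrap import BootstrapConfig
from echorobust.metrics import aggregate_sequences, macro_auc
from echorobust.models import HOGConfig, TrainedClassifier, predict_table, train_hog_svm
from echorobust.robustness import (
    DEFAULT_GRIDS,
    SeverityGrid,
    degradation_curve,
    failure_cases,
    learning_curve,
    subsample_training_sequences,
)
from tests.conftest import table_from_predictions

CLASSES = ["A2C", "A3C", "A4C", "A5C"]


class PixelStatClassifier(TrainedClassifier):
    """Cheap deterministic stand-in: reads simple intensity statistics."""

    def __init__(self):
        super().__init__(CLASSES, preprocessing="pixel-stats", seed=0)

    def predict_proba(self, frames):
        rows = []
        for f in frames:
            px = f.pixels
            stats = np.array([
                px.mean(), px.std(), (px > 0.5).mean(), np.abs(np.diff(px, axis=1)).mean(),
            ])
            z = 40.0 * stats
            e = np.exp(z - z.max())
            rows.append(e / e.sum())
        return np.asarray(rows)


@pytest.fixture(scope="module")
def hog_setup(request):
    """HOG+SVM trained on most of the small phantom dataset."""
    frames, labels, manifest = request.getfixturevalue("small_dataset")
    seqs = sorted(manifest["sequence_id"].unique())
    test_seqs = {s for i, s in enumerate(seqs) if i % 4 == 0}
    train_idx = [i for i, f in enumerate(frames) if f.sequence_id not in test_seqs]
    test_idx = [i for i, f in enumerate(frames) if f.sequence_id in test_seqs]
    model = train_hog_svm(
        [frames[i] for i in train_idx], [labels[i] for i in train_idx],
        HOGConfig(resize=64, pixels_per_cell=(8, 8)), seed=0,
    )
    return model, [frames[i] for i in test_idx], [labels[i] for i in test_idx]


class TestSeverityGrids:
    def test_default_grids_match_protocol(self):
        assert len(DEFAULT_GRIDS["motion_blur"].values) == 9
        np.testing.assert_allclose(
            DEFAULT_GRIDS["motion_blur"].values, np.arange(0, 20.1, 2.5)
        )
        np.testing.assert_allclose(
            DEFAULT_GRIDS["acoustic_shadow"].values, np.arange(0, 0.71, 0.1)
        )
        np.testing.assert_allclose(
            DEFAULT_GRIDS["speckle"].values, np.arange(0, 3.1, 0.5)
        )

    def test_grids_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            SeverityGrid("speckle", (0.5, 1.0))
        with pytest.raises(ValueError):
            SeverityGrid("speckle", (0.0, 1.0, 1.0))


class TestDegradationCurve:
    @pytest.fixture(scope="class")
    def blur_curve(self, request):
        frames, labels, _ = request.getfixturevalue("small_dataset")
        model = PixelStatClassifier()
        return degradation_curve(
            model, frames, labels,
            SeverityGrid("motion_blur", (0.0, 5.0, 20.0)),
            BootstrapConfig(B=200, seed=0), base_seed=1,
        )

    def test_zero_severity_row_is_exactly_null(self, blur_curve):
        for metric in ("macro_auc", "balanced_accuracy"):
            d = blur_curve.points[0].deltas[metric]
            assert d.delta == 0.0
            assert (d.ci_low, d.ci_high) == (0.0, 0.0)
            assert d.p_raw == 1.0 and d.p_holm == 1.0

    def test_zero_severity_reports_equal_baseline(self, blur_curve):
        base = blur_curve.points[0].frame_report
        table = blur_curve.baseline_table
        from echorobust.metrics import compute_report

        ref = compute_report(table)
        assert base.macro_auc == ref.macro_auc
        assert base.balanced_accuracy == ref.balanced_accuracy

    def test_holm_adjustment_spans_the_curve(self, blur_curve):
        raws = [p.deltas["macro_auc"].p_raw for p in blur_curve.points]
        holms = [p.deltas["macro_auc"].p_holm for p in blur_curve.points]
        from echorobust.bootstrap import holm_adjust

        np.testing.assert_allclose(holms, holm_adjust(raws))

    def test_serialized_table_has_protocol_columns(self, blur_curve):
        frame = blur_curve.to_frame("macro_auc")
        assert list(frame.columns) == [
            "severity", "baseline_macro_auc", "degraded_macro_auc", "delta",
            "ci_low", "ci_high", "p_value", "p_holm", "significant",
        ]
        assert len(frame) == 3

    def test_severe_speckle_hurts_macro_auc_more_than_mild(self, hog_setup):
        model, test_frames, test_labels = hog_setup
        curve = degradation_curve(
            model, test_frames, test_labels,
            SeverityGrid("speckle", (0.0, 0.5, 3.0)),
            BootstrapConfig(B=100, seed=0), base_seed=2,
        )
        auc = {p.severity: p.frame_report.macro_auc for p in curve.points}
        assert auc[3.0] < auc[0.5] <= auc[0.0] + 1e-9


class TestFailureCases:
    def _tables(self):
        y_true = ["A2C", "A3C", "A4C"]
        base_proba = np.array([
            [0.90, 0.04, 0.03, 0.03],
            [0.05, 0.75, 0.10, 0.10],  # correct but below threshold
            [0.02, 0.03, 0.92, 0.03],
        ])
        deg_proba = np.array([
            [0.02, 0.90, 0.04, 0.04],  # confident miss: delta -0.88
            [0.05, 0.05, 0.85, 0.05],  # missed, but baseline was not confident
            [0.01, 0.04, 0.90, 0.05],  # still correct
        ])
        from echorobust.metrics import make_table

        ids = ["s0", "s1", "s2"]
        base = make_table(ids, ids, y_true, base_proba, CLASSES)
        deg = make_table(ids, ids, y_true, deg_proba, CLASSES)
        return base, deg

    def test_identical_tables_yield_no_cases(self):
        base, _ = self._tables()
        assert len(failure_cases(base, base)) == 0

    def test_confident_baseline_miss_is_extracted_with_delta(self):
        base, deg = self._tables()
        cases = failure_cases(base, deg, threshold=0.8, family="speckle",
                              severity=3.0)
        assert len(cases) == 1
        row = cases.iloc[0]
        assert row["sequence_id"] == "s0"
        assert row["true_view"] == "A2C"
        assert row["degraded_predicted"] == "A3C"
        assert row["delta_true_prob"] == pytest.approx(-0.88)

    def test_unconfident_baseline_is_excluded_even_if_missed(self):
        base, deg = self._tables()
        cases = failure_cases(base, deg, threshold=0.8)
        assert "s1" not in set(cases["sequence_id"])


class TestLearningCurve:
    def test_stratified_sequence_subsampling(self):
        seqs = [f"{c}_s{i}" for c in CLASSES for i in range(8)]
        labels = {s: s.split("_")[0] for s in seqs}
        chosen = subsample_training_sequences(seqs, labels, 0.5, seed=0)
        assert len(chosen) == 16
        per_class = pd.Series([labels[s] for s in chosen]).value_counts()
        assert (per_class == 4).all()
        assert subsample_training_sequences(seqs, labels, 1.0, 0) == sorted(seqs)

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            subsample_training_sequences(["a"], {"a": "x"}, 0.0, 0)

    def test_grid_of_fractions_and_seeds(self, small_dataset):
        frames, labels, _ = small_dataset

        def trainer(sub_frames, sub_labels, seed):
            return PixelStatClassifier()

        lc = learning_curve(
            frames, labels, frames[:8], labels[:8], trainer,
            fractions=(0.5, 1.0), seeds=(0, 1, 2),
        )
        assert len(lc) == 6
        assert set(lc["fraction"]) == {0.5, 1.0}
        full = lc[lc["fraction"] == 1.0]
        assert full["n_train_sequences"].nunique() == 1

    def test_balanced_accuracy_improves_with_training_data(self, small_dataset):
        # scaled-down replication of the learning-curve trend: mean balanced
        # accuracy non-decreasing in the training fraction (one inversion
        # within noise tolerated)
        frames, labels, manifest = small_dataset
        seqs = sorted(manifest["sequence_id"].unique())
        test_seqs = {s for i, s in enumerate(seqs) if i % 4 == 0}
        train_idx = [i for i, f in enumerate(frames) if f.sequence_id not in test_seqs]
        test_idx = [i for i, f in enumerate(frames) if f.sequence_id in test_seqs]

        def trainer(sub_frames, sub_labels, seed):
            return train_hog_svm(sub_frames, sub_labels,
                                 HOGConfig(resize=64, pixels_per_cell=(8, 8)),
                                 seed=seed)

        lc = learning_curve(
            [frames[i] for i in train_idx], [labels[i] for i in train_idx],
            [frames[i] for i in test_idx], [labels[i] for i in test_idx],
            trainer, fractions=(0.34, 0.67, 1.0), seeds=(0, 1),
        )
        means = lc.groupby("fraction")["balanced_accuracy"].mean().to_numpy()
        drops = np.diff(means) < -0.10
        assert drops.sum() <= 1
        assert means[-1] >= means[0]
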