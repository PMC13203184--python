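"""Degradation curves, failure-case extraction, learning curves.

``degradation_curve`` runs the core experimental procedure: every test frame
is corrupted at each severity of an artifact's grid, the model re-predicts,
and the drop of each tracked metric relative to the severity-0 baseline is
quantified with the paired clustered bootstrap; p-values are Holm-adjusted
within the curve (all severities of one model x artifact table form the
family, severity 0 included).  Corruption touches evaluation inputs only —
training data are never degraded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from echorobust.artifacts import ArtifactSpec, apply_artifact
from echorobust.bootstrap import (
    BootstrapConfig,
    PairedDeltaResult,
    holm_adjust,
    paired_delta,
)
from echorobust.metrics import (
    MetricsReport,
    aggregate_sequences,
    balanced_accuracy_arrays,
    compute_report,
    macro_auc_arrays,
)
from echorobust.models import TrainedClassifier, predict_table
from echorobust.phantom import Frame


@dataclass(frozen=True)
class SeverityGrid:
    family: str
    values: tuple[float, ...]

    def __post_init__(self):
        v = self.values
        if len(v) == 0 or v[0] != 0.0:
            raise ValueError("severity grid must start at 0")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("severity grid must be strictly increasing")


DEFAULT_GRIDS = {
    "motion_blur": SeverityGrid("motion_blur", tuple(np.arange(0.0, 20.01, 2.5))),
    "acoustic_shadow": SeverityGrid(
        "acoustic_shadow", tuple(np.round(np.arange(0.0, 0.701, 0.1), 10))
    ),
    "speckle": SeverityGrid("speckle", tuple(np.arange(0.0, 3.01, 0.5))),
}

# metric name -> (level, array metric); "sequence" metrics are computed on
# the sequence-aggregated table, matching the study's reporting levels.
TRACKED_METRICS = {
    "macro_auc": ("frame", macro_auc_arrays),
    "balanced_accuracy": ("sequence", balanced_accuracy_arrays),
}


@dataclass
class CurvePoint:
    severity: float
    frame_report: MetricsReport
    sequence_report: MetricsReport
    deltas: dict[str, PairedDeltaResult] = field(default_factory=dict)


@dataclass
class DegradationCurve:
    family: str
    points: list[CurvePoint]
    baseline_table: pd.DataFrame
    tables: dict[float, pd.DataFrame]

    def to_frame(self, metric: str = "macro_auc") -> pd.DataFrame:
        """CSV-ready table: severity, baseline, degraded, delta, CI, raw and
        Holm-adjusted p, significance flag."""
        level, _ = TRACKED_METRICS[metric]
        rows = []
        for pt in self.points:
            report = pt.frame_report if level == "frame" else pt.sequence_report
            baseline_report = (
                self.points[0].frame_report if level == "frame"
                else self.points[0].sequence_report
            )
            base = getattr(baseline_report, metric)
            d = pt.deltas[metric]
            rows.append(
                {
                    "severity": pt.severity,
                    f"baseline_{metric}": base,
                    f"degraded_{metric}": getattr(report, metric),
                    "delta": d.delta,
                    "ci_low": d.ci_low,
                    "ci_high": d.ci_high,
                    "p_value": d.p_raw,
                    "p_holm": d.p_holm,
                    "significant": d.significant,
                }
            )
        return pd.DataFrame(rows)


def degradation_curve(
    model: TrainedClassifier,
    frames: list[Frame],
    labels: list[str],
    grid: SeverityGrid,
    boot: BootstrapConfig,
    base_seed: int = 0,
) -> DegradationCurve:
    """Corrupt -> predict -> measure -> paired bootstrap, per severity.

    The severity-0 predictions are computed once and serve as the shared
    baseline; its delta row is exactly 0 with CI [0, 0] and p = 1.
    """
    baseline = predict_table(model, frames, labels)
    points: list[CurvePoint] = []
    tables: dict[float, pd.DataFrame] = {}
    for severity in grid.values:
        if severity == 0.0:
            table = baseline
        else:
            corrupted = [
                apply_artifact(f, ArtifactSpec(grid.family, float(severity)), base_seed)
                for f in frames
            ]
            table = predict_table(model, corrupted, labels)
        tables[float(severity)] = table
        point = CurvePoint(
            severity=float(severity),
            frame_report=compute_report(table),
            sequence_report=compute_report(aggregate_sequences(table)),
        )
        for name, (level, metric_fn) in TRACKED_METRICS.items():
            if level == "frame":
                a, b = baseline, table
            else:
                a, b = aggregate_sequences(baseline), aggregate_sequences(table)
            point.deltas[name] = paired_delta(a, b, metric_fn, boot)
        points.append(point)
    for name in TRACKED_METRICS:
        raw = [pt.deltas[name].p_raw for pt in points]
        adjusted = holm_adjust(raw)
        for pt, p in zip(points, adjusted):
            pt.deltas[name].p_holm = float(p)
    return DegradationCurve(
        family=grid.family, points=points, baseline_table=baseline, tables=tables
    )


def failure_cases(
    baseline: pd.DataFrame,
    degraded: pd.DataFrame,
    threshold: float = 0.8,
    family: str | None = None,
    severity: float | None = None,
) -> pd.DataFrame:
    """Units (sequences, typically) confidently correct at baseline
    (true-class probability > ``threshold``) but misclassified after
    degradation.  ``delta_true_prob = degraded - baseline`` probability of
    the true class; rows sorted by that drop, largest first in magnitude."""
    from echorobust.bootstrap import _check_aligned
    from echorobust.metrics import PROB_PREFIX

    base, deg = _check_aligned(baseline, degraded)
    rows = []
    for i in range(len(base)):
        true = base.at[i, "true_label"]
        p_base = base.at[i, PROB_PREFIX + true]
        p_deg = deg.at[i, PROB_PREFIX + true]
        if (
            base.at[i, "predicted_label"] == true
            and p_base > threshold
            and deg.at[i, "predicted_label"] != true
        ):
            rows.append(
                {
                    "sequence_id": base.at[i, "sequence_id"],
                    "artifact": family,
                    "severity": severity,
                    "true_view": true,
                    "baseline_predicted": base.at[i, "predicted_label"],
                    "baseline_true_prob": float(p_base),
                    "degraded_predicted": deg.at[i, "predicted_label"],
                    "degraded_true_prob": float(p_deg),
                    "delta_true_prob": float(p_deg - p_base),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "artifact", "severity", "true_view",
            "baseline_predicted", "baseline_true_prob",
            "degraded_predicted", "degraded_true_prob", "delta_true_prob",
        ],
    )
    return out.sort_values("delta_true_prob").reset_index(drop=True)


def subsample_training_sequences(
    train_sequences: list[str],
    labels_by_sequence: dict[str, str],
    fraction: float,
    seed: int,
) -> list[str]:
    """Stratified sequence-level subsample of the training split."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return sorted(train_sequences)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    by_class: dict[str, list[str]] = {}
    for s in sorted(train_sequences):
        by_class.setdefault(labels_by_sequence[s], []).append(s)
    for label in sorted(by_class):
        seqs = by_class[label]
        k = max(1, int(round(fraction * len(seqs))))
        order = rng.permutation(len(seqs))
        chosen.extend(seqs[i] for i in order[:k])
    return sorted(chosen)


def learning_curve(
    train_frames: list[Frame],
    train_labels: list[str],
    test_frames: list[Frame],
    test_labels: list[str],
    trainer,
    fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0),
    seeds: tuple[int, ...] = (0, 1, 2),
) -> pd.DataFrame:
    """Balanced accuracy (sequence level) vs training-set size.

    Training subsets are drawn by stratified *sequence* subsampling (no new
    leakage); validation and test sets are untouched.  ``trainer`` is a
    callable ``(frames, labels, seed) -> TrainedClassifier``.
    """
    labels_by_seq: dict[str, str] = {}
    for fr, lab in zip(train_frames, train_labels):
        labels_by_seq[fr.sequence_id] = lab
    all_seqs = sorted(labels_by_seq)
    rows = []
    for fraction in fractions:
        for seed in seeds:
            chosen = set(
                subsample_training_sequences(all_seqs, labels_by_seq, fraction, seed)
            )
            sub_frames = [f for f in train_frames if f.sequence_id in chosen]
            sub_labels = [
                l for f, l in zip(train_frames, train_labels) if f.sequence_id in chosen
            ]
            if len(set(sub_labels)) < len(set(train_labels)):
                raise ValueError(
                    f"fraction {fraction} dropped a class entirely; increase it"
                )
            model = trainer(sub_frames, sub_labels, seed)
            table = aggregate_sequences(predict_table(model, test_frames, test_labels))
            from echorobust.metrics import balanced_accuracy

            rows.append(
                {
                    "fraction": fraction,
                    "seed": seed,
                    "n_train_sequences": len(chosen),
                    "n_train_frames": len(sub_frames),
                    "balanced_accuracy": balanced_accuracy(table),
                }
            )
    return pd.DataFrame(rows)
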