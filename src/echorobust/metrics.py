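"""Frame- and sequence-level evaluation metrics from prediction tables.

A *prediction table* is a DataFrame with one row per frame (or sequence):
``frame_id, sequence_id, true_label, p_<class>... , predicted_label`` where
the probability columns sum to one and ``predicted_label`` is the argmax
(ties broken by lowest class index).  It is the sole input of every metric
and of the bootstrap machinery.

Balanced accuracy is the unweighted mean of per-class recalls; macro-AUC is
the unweighted mean of one-vs-rest AUCs computed with the rank statistic
(midrank tie handling, equivalent to the trapezoidal ROC area).  Classes
absent from a table (possible in bootstrap replicates when a rare class's
sequences are not drawn) are dropped from balanced accuracy and macro means
rather than counted as zero recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

PROB_PREFIX = "p_"


def prob_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith(PROB_PREFIX)]


def table_classes(table: pd.DataFrame) -> list[str]:
    return [c[len(PROB_PREFIX):] for c in prob_columns(table)]


def make_table(
    frame_ids,
    sequence_ids,
    true_labels,
    proba: np.ndarray,
    classes: list[str],
) -> pd.DataFrame:
    """Assemble a prediction table; the argmax column is derived, with ties
    resolved to the lowest class index."""
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or proba.shape[1] != len(classes):
        raise ValueError("probability matrix shape does not match classes")
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    table = pd.DataFrame(
        {
            "frame_id": list(frame_ids),
            "sequence_id": list(sequence_ids),
            "true_label": list(true_labels) if true_labels is not None else None,
        }
    )
    for j, c in enumerate(classes):
        table[PROB_PREFIX + c] = proba[:, j]
    table["predicted_label"] = [classes[j] for j in proba.argmax(axis=1)]
    return table


def extract_arrays(table: pd.DataFrame):
    """(true codes, probability matrix, classes) for fast metric evaluation.

    True labels outside the model's class list are given code -1 (they can
    never be predicted correctly but still count as support for errors).
    """
    classes = table_classes(table)
    index = {c: i for i, c in enumerate(classes)}
    y_true = np.array([index.get(t, -1) for t in table["true_label"]], dtype=int)
    proba = table[prob_columns(table)].to_numpy(dtype=float)
    return y_true, proba, classes


def balanced_accuracy_arrays(y_true: np.ndarray, proba: np.ndarray) -> float:
    """Mean per-class recall over the classes present in ``y_true``."""
    y_pred = proba.argmax(axis=1)
    present = np.unique(y_true[y_true >= 0])
    if present.size == 0:
        return float("nan")
    recalls = [
        float((y_pred[y_true == k] == k).mean()) for k in present
    ]
    return float(np.mean(recalls))


def auc_ovr_arrays(y_true: np.ndarray, proba: np.ndarray) -> np.ndarray:
    """One-vs-rest AUC per class via the Mann-Whitney rank statistic.

    Midranks handle ties (equivalent to trapezoidal ROC area).  Classes with
    no positives or no negatives get NaN.
    """
    n, K = proba.shape
    out = np.full(K, np.nan)
    for k in range(K):
        pos = y_true == k
        n_pos = int(pos.sum())
        n_neg = n - n_pos
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = rankdata(proba[:, k])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        out[k] = u / (n_pos * n_neg)
    return out


def macro_auc_arrays(y_true: np.ndarray, proba: np.ndarray) -> float:
    aucs = auc_ovr_arrays(y_true, proba)
    defined = aucs[~np.isnan(aucs)]
    if defined.size == 0:
        return float("nan")
    return float(defined.mean())


def balanced_accuracy(table: pd.DataFrame) -> float:
    y_true, proba, _ = extract_arrays(table)
    return balanced_accuracy_arrays(y_true, proba)


def auc_ovr(table: pd.DataFrame) -> tuple[dict[str, float], float]:
    """Per-class OvR AUC and the macro average over defined classes."""
    y_true, proba, classes = extract_arrays(table)
    aucs = auc_ovr_arrays(y_true, proba)
    if np.isnan(aucs).any():
        undefined = [c for c, a in zip(classes, aucs) if np.isnan(a)]
        warnings.warn(
            f"AUC undefined for classes without positives/negatives: {undefined}; "
            "macro-AUC computed over the remaining classes"
        )
    per_class = {c: float(a) for c, a in zip(classes, aucs)}
    macro = float(np.nanmean(aucs)) if not np.isnan(aucs).all() else float("nan")
    return per_class, macro


def macro_auc(table: pd.DataFrame) -> float:
    return auc_ovr(table)[1]


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1/AUC/support plus global summaries."""

    per_class: pd.DataFrame  # index: class; columns: precision, recall, f1, auc, support
    accuracy: float
    balanced_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auc: float
    confusion: pd.DataFrame  # rows true, columns predicted

    def to_json_dict(self) -> dict:
        return {
            "per_class": self.per_class.to_dict(orient="index"),
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "confusion": self.confusion.to_dict(orient="index"),
        }

    def to_table(self) -> pd.DataFrame:
        """Per-class rows plus accuracy / balanced-accuracy footer rows."""
        rows = self.per_class.reset_index(names="class")
        footer = pd.DataFrame(
            [
                {"class": "accuracy", "precision": np.nan, "recall": np.nan,
                 "f1": self.accuracy, "auc": np.nan,
                 "support": int(self.per_class["support"].sum())},
                {"class": "balanced accuracy", "precision": np.nan, "recall": np.nan,
                 "f1": self.balanced_accuracy, "auc": np.nan,
                 "support": int(self.per_class["support"].sum())},
            ]
        )
        return pd.concat([rows, footer], ignore_index=True)


def compute_report(table: pd.DataFrame) -> MetricsReport:
    """All frame-level quantities: per-class precision/recall/F1 (F1 = 0 at
    P = R = 0), OvR AUC, accuracy, balanced accuracy, unweighted macro
    averages, confusion matrix."""
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

    if len(table) == 0:
        raise ValueError("empty prediction table")
    classes = table_classes(table)
    y_true = table["true_label"].to_numpy()
    y_pred = table["predicted_label"].to_numpy()
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    auc_per_class, macro = auc_ovr(table)
    per_class = pd.DataFrame(
        {
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "auc": [auc_per_class[c] for c in classes],
            "support": support,
        },
        index=pd.Index(classes, name="class"),
    )
    present = per_class["support"] > 0
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    return MetricsReport(
        per_class=per_class,
        accuracy=float((y_true == y_pred).mean()),
        balanced_accuracy=float(per_class.loc[present, "recall"].mean()),
        macro_precision=float(per_class.loc[present, "precision"].mean()),
        macro_recall=float(per_class.loc[present, "recall"].mean()),
        macro_f1=float(per_class.loc[present, "f1"].mean()),
        macro_auc=macro,
        confusion=pd.DataFrame(cm, index=pd.Index(classes, name="true"),
                               columns=pd.Index(classes, name="predicted")),
    )


def aggregate_sequences(table: pd.DataFrame) -> pd.DataFrame:
    """Average frame probabilities within each sequence; the sequence label
    is the class with the highest mean probability (ties -> lowest index)."""
    cols = prob_columns(table)
    labels = table.groupby("sequence_id")["true_label"].nunique()
    if (labels > 1).any():
        raise ValueError("sequences with inconsistent true labels")
    grouped = table.groupby("sequence_id", sort=True)
    means = grouped[cols].mean()
    truth = grouped["true_label"].first()
    classes = table_classes(table)
    out = pd.DataFrame(
        {
            "frame_id": means.index,
            "sequence_id": means.index,
            "true_label": truth.loc[means.index].to_numpy(),
        }
    )
    for c in cols:
        out[c] = means[c].to_numpy()
    out["predicted_label"] = [
        classes[j] for j in means.to_numpy().argmax(axis=1)
    ]
    return out.reset_index(drop=True)


def round_half_up(x: float, digits: int = 3) -> float:
    """Half-up rounding used for formatted report output (0.8665 -> 0.867).

    Binary float error is absorbed at 9 decimals first, so a value that is
    mathematically 0.8665 but stored as 0.86649999... still rounds up.
    """
    import decimal

    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal("1e-9"), rounding=decimal.ROUND_HALF_EVEN
    )
    d = d.quantize(
        decimal.Decimal("1." + "0" * digits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)
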