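"""Sequence-clustered bootstrap inference.

Frames from one clip are temporally correlated, so all resampling happens at
the sequence (cluster) level: a bootstrap replicate draws sequences with
replacement (same count as the original) and keeps every frame of each drawn
sequence.  Three procedures are provided:

* ``clustered_bootstrap_ci`` — percentile CI of a metric,
* ``paired_delta`` — the paired design for degradation effects: each
  replicate's sequence draw drives *both* the baseline and the degraded
  table, so shared cluster noise cancels from the difference
  ``delta = metric(degraded) - metric(baseline)``,
* ``compare_models`` — the same machinery for between-model contrasts.

Empirical two-sided p-values use the add-one rule
``p = min(1, 2 * min(#{d* >= 0} + 1, #{d* <= 0} + 1) / (B + 1))`` so a
degenerate all-zero replicate distribution yields p = 1 and an extreme
one-sided distribution yields p ~ 2/(B+1).  Families of p-values across the
severity levels of one degradation curve are adjusted with the Holm
step-down procedure.  CI endpoints are linear-interpolation percentiles
(numpy's default), recorded in the result metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from echorobust.metrics import extract_arrays

MetricFn = Callable[[np.ndarray, np.ndarray], float]


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class BootstrapCI:
    point: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray
    percentile_convention: str = "linear-interpolation"


@dataclass
class PairedDeltaResult:
    delta: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_holm: float | None = None
    alpha: float = 0.05
    replicates: np.ndarray | None = field(default=None, repr=False)
    percentile_convention: str = "linear-interpolation"

    @property
    def significant(self) -> bool:
        p = self.p_holm if self.p_holm is not None else self.p_raw
        return bool(p < self.alpha)


def _cluster_index(table: pd.DataFrame) -> list[np.ndarray]:
    """Row indices per sequence, in sorted sequence order."""
    groups = table.groupby("sequence_id", sort=True).indices
    return [np.asarray(groups[k], dtype=int) for k in sorted(groups)]


def empirical_p(replicates: np.ndarray) -> float:
    """Two-sided add-one empirical p-value of the replicate deltas."""
    d = np.asarray(replicates, dtype=float)
    B = d.size
    n_ge = int((d >= 0).sum()) + 1
    n_le = int((d <= 0).sum()) + 1
    return min(1.0, 2.0 * min(n_ge, n_le) / (B + 1))


def clustered_bootstrap_ci(
    table: pd.DataFrame, metric: MetricFn, config: BootstrapConfig
) -> BootstrapCI:
    """Percentile CI of ``metric`` under sequence-level resampling.

    ``metric`` takes (true-label codes, probability matrix).  Replicates on
    which the metric is undefined (e.g. no class present) are dropped with a
    warning — the metric itself already implements the absent-class policy.
    """
    y_true, proba, _ = extract_arrays(table)
    clusters = _cluster_index(table)
    S = len(clusters)
    point = float(metric(y_true, proba))
    if S < 2:
        warnings.warn("only one sequence: degenerate CI equal to the point estimate")
        reps = np.full(config.B, point)
        return BootstrapCI(point, point, point, reps)
    rng = np.random.default_rng(config.seed)
    reps = np.empty(config.B)
    for b in range(config.B):
        draw = rng.integers(0, S, size=S)
        rows = np.concatenate([clusters[i] for i in draw])
        reps[b] = metric(y_true[rows], proba[rows])
    finite = reps[np.isfinite(reps)]
    if finite.size < reps.size:
        warnings.warn(
            f"{reps.size - finite.size} replicates had an undefined metric and were dropped"
        )
    lo, hi = np.percentile(
        finite, [100 * config.alpha / 2, 100 * (1 - config.alpha / 2)]
    )
    return BootstrapCI(point, float(lo), float(hi), reps)


def _check_aligned(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    a = a.sort_values("frame_id").reset_index(drop=True)
    b = b.sort_values("frame_id").reset_index(drop=True)
    if len(a) != len(b) or not (a["frame_id"].to_numpy() == b["frame_id"].to_numpy()).all():
        raise ValueError("tables must cover identical frame_ids")
    if not (a["sequence_id"].to_numpy() == b["sequence_id"].to_numpy()).all():
        raise ValueError("tables must share sequence assignments")
    if not (a["true_label"].to_numpy() == b["true_label"].to_numpy()).all():
        raise ValueError("tables must share true labels")
    return a, b


def _paired_bootstrap(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metric: MetricFn,
    config: BootstrapConfig,
) -> PairedDeltaResult:
    """delta = metric(b) - metric(a); one sequence draw drives both tables."""
    table_a, table_b = _check_aligned(table_a, table_b)
    y_a, p_a, _ = extract_arrays(table_a)
    y_b, p_b, _ = extract_arrays(table_b)
    clusters = _cluster_index(table_a)
    S = len(clusters)
    delta = float(metric(y_b, p_b)) - float(metric(y_a, p_a))
    rng = np.random.default_rng(config.seed)
    reps = np.empty(config.B)
    for b in range(config.B):
        draw = rng.integers(0, S, size=S)
        rows = np.concatenate([clusters[i] for i in draw])
        reps[b] = metric(y_b[rows], p_b[rows]) - metric(y_a[rows], p_a[rows])
    finite = reps[np.isfinite(reps)]
    if finite.size < reps.size:
        warnings.warn(
            f"{reps.size - finite.size} replicates had an undefined metric and were dropped"
        )
    lo, hi = np.percentile(
        finite, [100 * config.alpha / 2, 100 * (1 - config.alpha / 2)]
    )
    return PairedDeltaResult(
        delta=delta,
        ci_low=float(lo),
        ci_high=float(hi),
        p_raw=empirical_p(finite),
        alpha=config.alpha,
        replicates=reps,
    )


def paired_delta(
    baseline: pd.DataFrame,
    degraded: pd.DataFrame,
    metric: MetricFn,
    config: BootstrapConfig,
) -> PairedDeltaResult:
    """Paired clustered bootstrap for a degradation effect
    (delta = degraded - baseline, matching the negative-delta convention of
    degradation tables)."""
    return _paired_bootstrap(baseline, degraded, metric, config)


def compare_models(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metric: MetricFn,
    config: BootstrapConfig,
) -> PairedDeltaResult:
    """Between-model contrast on the same frames: delta = metric(B) - metric(A)."""
    return _paired_bootstrap(table_a, table_b, metric, config)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment, returned in the original order.

    Sort ascending; ``adjusted(i) = min(1, max_{j <= i} (m - j + 1) p(j))``
    (1-based j), which enforces monotonicity along the sorted order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted
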