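"""End-to-end experiment driver: generate -> split -> train -> evaluate ->
degradation curves -> failure cases -> (optional) learning curve.

Every stage logs its seed; a completed run directory contains the resolved
configuration and is sufficient to reproduce itself byte for byte.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import pandas as pd

from echorobust.bootstrap import BootstrapConfig
from echorobust.config import RunConfig, stage_seed
from echorobust.data import make_split
from echorobust.metrics import aggregate_sequences, compute_report
from echorobust.models import predict_table, train_hog_svm, train_small_cnn
from echorobust.phantom import generate_dataset, iter_sequences
from echorobust.robustness import (
    DEFAULT_GRIDS,
    SeverityGrid,
    degradation_curve,
    failure_cases,
    learning_curve,
)

log = logging.getLogger("echorobust")


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(out_dir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def generate_in_memory(config: RunConfig):
    """Generate the phantom dataset in memory: (frames, labels, manifest)."""
    phantom_cfg = config.phantom_config()
    seed = stage_seed(config.seed, "generate")
    frames, labels, rows = [], [], []
    for seq in iter_sequences(phantom_cfg, seed):
        for fr in seq.frames:
            frames.append(fr)
            labels.append(seq.view.label)
            rows.append(
                {
                    "frame_id": fr.frame_id,
                    "sequence_id": fr.sequence_id,
                    "label": seq.view.label,
                    "frame_index": fr.frame_index,
                    "path": "",
                }
            )
    return frames, labels, pd.DataFrame(rows)


def train_classifier(config: RunConfig, train_frames, train_labels,
                     val_frames, val_labels):
    seed = stage_seed(config.seed, "train")
    if config.classifier == "hog_svm":
        return train_hog_svm(train_frames, train_labels, config.hog_config(), seed)
    if config.classifier == "small_cnn":
        return train_small_cnn(
            train_frames, train_labels, val_frames, val_labels,
            config.cnn_config(), seed,
        )
    raise ValueError(f"unknown classifier {config.classifier!r}")


def run_experiment(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    config.dump(out / "config.json")
    stage = "init"
    try:
        stage = "generate"
        t0 = time.time()
        frames, labels, manifest = generate_in_memory(config)
        log.info("generate: %d frames, %d sequences (seed %d, %.1fs)",
                 len(frames), manifest.sequence_id.nunique(),
                 stage_seed(config.seed, "generate"), time.time() - t0)
        if config.save_frames:
            generate_dataset(config.phantom_config(),
                             stage_seed(config.seed, "generate"), out / "dataset")

        stage = "split"
        split = make_split(
            manifest,
            test_fraction=config.test_fraction,
            validation_fraction=config.validation_fraction,
            seed=stage_seed(config.seed, "split"),
            sequence_level_validation=config.sequence_level_validation,
        )
        split.to_json(out / "split.json")
        by_id = dict(zip(manifest.frame_id, zip(frames, labels)))

        def part(name):
            ids = split.frames(manifest, name)["frame_id"].tolist()
            return [by_id[i][0] for i in ids], [by_id[i][1] for i in ids]

        train_fit, train_fit_labels = part("train_fit")
        val, val_labels = part("validation")
        test, test_labels = part("test")
        log.info("split: %d train-fit / %d validation frames, %d test frames "
                 "in %d sequences (seed %d)",
                 len(train_fit), len(val), len(test),
                 len({f.sequence_id for f in test}), stage_seed(config.seed, "split"))

        stage = "train"
        t0 = time.time()
        model = train_classifier(config, train_fit, train_fit_labels, val, val_labels)
        log.info("train: %s on %d frames (seed %d, %.1fs)", config.classifier,
                 len(train_fit), stage_seed(config.seed, "train"), time.time() - t0)

        stage = "baseline"
        baseline_table = predict_table(model, test, test_labels)
        frame_report = compute_report(baseline_table)
        seq_report = compute_report(aggregate_sequences(baseline_table))
        (out / "metrics_baseline.json").write_text(json.dumps(
            {"frame": frame_report.to_json_dict(),
             "sequence": seq_report.to_json_dict()}, indent=1))
        baseline_table.to_csv(out / "predictions_baseline.csv", index=False)
        log.info("baseline: frame balanced accuracy %.3f, sequence %.3f, "
                 "frame macro-AUC %.3f", frame_report.balanced_accuracy,
                 seq_report.balanced_accuracy, frame_report.macro_auc)

        stage = "curves"
        boot = BootstrapConfig(B=config.bootstrap.B, alpha=config.bootstrap.alpha,
                               seed=stage_seed(config.seed, "bootstrap"))
        curves_dir = out / "curves" / config.classifier
        curves_dir.mkdir(parents=True, exist_ok=True)
        all_failures = []
        for family in config.artifacts:
            grid = (
                SeverityGrid(family, tuple(config.grids[family]))
                if family in config.grids
                else DEFAULT_GRIDS[family]
            )
            t0 = time.time()
            curve = degradation_curve(
                model, test, test_labels, grid, boot,
                base_seed=stage_seed(config.seed, f"corrupt:{family}"),
            )
            for metric in ("macro_auc", "balanced_accuracy"):
                curve.to_frame(metric).to_csv(
                    curves_dir / f"{family}_{metric}.csv", index=False
                )
            worst = grid.values[-1]
            fc = failure_cases(
                aggregate_sequences(curve.baseline_table),
                aggregate_sequences(curve.tables[worst]),
                threshold=config.failure_threshold,
                family=family, severity=worst,
            )
            all_failures.append(fc)
            log.info("curve %s: %d severities, %d failure cases at %.3g (%.1fs)",
                     family, len(grid.values), len(fc), worst, time.time() - t0)
        pd.concat(all_failures, ignore_index=True).to_csv(
            out / "failures.csv", index=False
        )

        if config.learning_curve is not None:
            stage = "learning_curve"
            lc_seed = stage_seed(config.seed, "learning_curve")

            def trainer(fr, lb, seed):
                return train_classifier(config, fr, lb, val, val_labels)

            lc = learning_curve(
                train_fit, train_fit_labels, test, test_labels, trainer,
                fractions=tuple(config.learning_curve.fractions),
                seeds=tuple(lc_seed + i for i in range(config.learning_curve.n_seeds)),
            )
            lc.to_csv(out / "learning_curve.csv", index=False)
            log.info("learning curve: %d rows", len(lc))
        return out
    except Exception:
        log.exception("stage %r failed; partial outputs kept in %s", stage, out)
        raise


REQUIRED_ARTIFACTS = ["config.json", "metrics_baseline.json", "failures.csv"]


def run_report(results_dir: Path | str) -> str:
    """Render the stored run artifacts as human-readable tables.

    Raises FileNotFoundError listing missing artifacts for incomplete runs.
    """
    results = Path(results_dir)
    missing = [name for name in REQUIRED_ARTIFACTS if not (results / name).exists()]
    curve_files = sorted(results.glob("curves/*/*.csv"))
    if not curve_files:
        missing.append("curves/<model>/<artifact>_<metric>.csv")
    if missing:
        raise FileNotFoundError(f"incomplete results directory, missing: {missing}")
    chunks = []
    baseline = json.loads((results / "metrics_baseline.json").read_text())
    for level in ("frame", "sequence"):
        rep = baseline[level]
        per_class = pd.DataFrame.from_dict(rep["per_class"], orient="index")
        chunks.append(f"== Baseline metrics ({level} level) ==")
        chunks.append(per_class.round(3).to_string())
        chunks.append(f"accuracy          {rep['accuracy']:.3f}")
        chunks.append(f"balanced accuracy {rep['balanced_accuracy']:.3f}")
        chunks.append(f"macro-AUC         {rep['macro_auc']:.3f}")
        chunks.append("")
    for path in curve_files:
        chunks.append(f"== Degradation: {path.parent.name} / {path.stem} ==")
        chunks.append(pd.read_csv(path).round(3).to_string(index=False))
        chunks.append("")
    failures = pd.read_csv(results / "failures.csv")
    chunks.append(f"== Failure cases (n={len(failures)}) ==")
    if len(failures):
        chunks.append(failures.round(3).to_string(index=False))
    lc_path = results / "learning_curve.csv"
    if lc_path.exists():
        lc = pd.read_csv(lc_path)
        chunks.append("")
        chunks.append("== Learning curve ==")
        chunks.append(
            lc.groupby("fraction")["balanced_accuracy"]
            .agg(["mean", "std"]).round(3).to_string()
        )
    return "\n".join(chunks)
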