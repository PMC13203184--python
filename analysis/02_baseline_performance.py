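"""Reference-condition performance of both classifiers on clean phantoms.

Generates the study dataset in memory, applies the sequence-level 80/20
train/test split (frame-level 20% validation inside training), trains the
HOG+SVM baseline and the small CNN, and writes per-class
precision/recall/F1/AUC tables with accuracy and balanced-accuracy footers
(frame level and sequence level) under results/baseline/.

Usage: python analysis/02_baseline_performance.py [--seed 0]
"""

import argparse
import json
from pathlib import Path

from echorobust.config import RunConfig, stage_seed
from echorobust.data import make_split
from echorobust.experiment import generate_in_memory, train_classifier
from echorobust.metrics import aggregate_sequences, compute_report
from echorobust.models import predict_table


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/baseline"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    base = RunConfig.study(seed=args.seed)
    frames, labels, manifest = generate_in_memory(base)
    split = make_split(manifest, seed=stage_seed(args.seed, "split"))
    by_id = dict(zip(manifest.frame_id, zip(frames, labels)))

    def part(name):
        ids = split.frames(manifest, name)["frame_id"].tolist()
        return [by_id[i][0] for i in ids], [by_id[i][1] for i in ids]

    train_fit, train_labels = part("train_fit")
    val, val_labels = part("validation")
    test, test_labels = part("test")
    print(f"{len(train_fit)} training / {len(val)} validation / "
          f"{len(test)} test frames")

    for name in ("hog_svm", "small_cnn"):
        config = RunConfig.study(classifier=name, seed=args.seed)
        model = train_classifier(config, train_fit, train_labels, val, val_labels)
        table = predict_table(model, test, test_labels)
        frame_report = compute_report(table)
        seq_report = compute_report(aggregate_sequences(table))
        frame_report.to_table().round(3).to_csv(
            args.out / f"{name}_frame_metrics.csv", index=False
        )
        seq_report.to_table().round(3).to_csv(
            args.out / f"{name}_sequence_metrics.csv", index=False
        )
        (args.out / f"{name}_metrics.json").write_text(json.dumps(
            {"frame": frame_report.to_json_dict(),
             "sequence": seq_report.to_json_dict()}, indent=1))
        print(f"\n== {name} ==")
        print(frame_report.to_table().round(3).to_string(index=False))
        print(f"sequence-level balanced accuracy: "
              f"{seq_report.balanced_accuracy:.3f}")


if __name__ == "__main__":
    main()
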