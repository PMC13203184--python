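"""Learning curve: balanced accuracy vs training-set size.

Trains the HOG+SVM baseline on stratified sequence-level subsets (25%, 50%,
75%, 100% of the training split) over several seeds, evaluating
sequence-level balanced accuracy on the untouched test split, and writes
results/learning_curve.csv plus a per-fraction summary.

Usage: python analysis/05_learning_curve.py [--seed 0] [--n-seeds 3]
"""

import argparse
from pathlib import Path

from echorobust.config import RunConfig, stage_seed
from echorobust.data import make_split
from echorobust.experiment import generate_in_memory
from echorobust.models import HOGConfig, train_hog_svm
from echorobust.robustness import learning_curve


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-seeds", type=int, default=3)
    parser.add_argument("--out", type=Path, default=Path("results/learning_curve.csv"))
    args = parser.parse_args()

    config = RunConfig.study(classifier="hog_svm", seed=args.seed)
    frames, labels, manifest = generate_in_memory(config)
    split = make_split(manifest, seed=stage_seed(args.seed, "split"))
    by_id = dict(zip(manifest.frame_id, zip(frames, labels)))

    def part(name):
        ids = split.frames(manifest, name)["frame_id"].tolist()
        return [by_id[i][0] for i in ids], [by_id[i][1] for i in ids]

    train_fit, train_labels = part("train_fit")
    test, test_labels = part("test")

    def trainer(sub_frames, sub_labels, seed):
        return train_hog_svm(sub_frames, sub_labels, HOGConfig(), seed=seed)

    base = stage_seed(args.seed, "learning_curve")
    table = learning_curve(
        train_fit, train_labels, test, test_labels, trainer,
        fractions=(0.25, 0.5, 0.75, 1.0),
        seeds=tuple(base + i for i in range(args.n_seeds)),
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(table.groupby("fraction")["balanced_accuracy"]
          .agg(["mean", "std"]).round(3).to_string())


if __name__ == "__main__":
    main()
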