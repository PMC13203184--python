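"""Degradation curves: artifact type x severity -> performance drop.

For each classifier and each artifact family (horizontal motion blur,
conical acoustic shadowing, multiplicative speckle), corrupts every test
frame over the full severity grid, recomputes frame-level macro-AUC and
sequence-level balanced accuracy, and quantifies the drop against the
severity-0 baseline with the paired clustered bootstrap (B = 1000) and
Holm-adjusted empirical p-values.  Writes one CSV per
(model, artifact, metric) under results/run-<model>/curves/.

This is the core experiment.  Expect ~10 minutes for the HOG+SVM pipeline
and ~20 for the CNN on one CPU.

Usage: python analysis/03_degradation_curves.py [--seed 0] [--model hog_svm]
"""

import argparse

from echorobust.config import RunConfig
from echorobust.experiment import run_experiment


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--model", choices=["hog_svm", "small_cnn", "both"],
                        default="both")
    args = parser.parse_args()

    models = ["hog_svm", "small_cnn"] if args.model == "both" else [args.model]
    for name in models:
        config = RunConfig.study(classifier=name, seed=args.seed,
                                 out_dir=f"results/run-{name}")
        out = run_experiment(config)
        print(f"{name}: results in {out}")


if __name__ == "__main__":
    main()
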