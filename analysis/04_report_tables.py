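"""Render the stored run directories as human-readable tables.

Prints the baseline per-class metric tables, the delta tables
(severity, baseline, degraded, delta, 95% CI, raw and Holm-adjusted p,
significance) for every artifact, and the failure-case list.

Usage: python analysis/04_report_tables.py [results/run-hog_svm ...]
"""

import sys
from pathlib import Path

from echorobust.experiment import run_report


def main() -> None:
    dirs = [Path(p) for p in sys.argv[1:]] or sorted(Path("results").glob("run-*"))
    if not dirs:
        sys.exit("no results directories found; run 03_degradation_curves.py first")
    for d in dirs:
        print(f"#### {d} ####")
        print(run_report(d))
        print()


if __name__ == "__main__":
    main()
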