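#!/usr/bin/env python
"""Paired pre/post comparison of the seven accuracy metrics.

Compares AA1 (post-MRI) with AA2 (post-3D-model) per metric — paired t-test
for the continuous metrics, Wilcoxon signed-rank for the 0-4 scores — and
stratifies the linear-incision deviation by group (residents vs interns),
where only residents are simulated to improve. Writes comparison tables
under results/ and prints the human-readable report.
"""

import sys
from pathlib import Path

from neuroplan import io as npio
from neuroplan.io import RunConfig
from neuroplan.pipeline import compare_metrics, _report_text

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    metrics_csv = OUT / "metrics.csv"
    if not metrics_csv.exists():
        print("run 03_assess_cohort.py first", file=sys.stderr)
        return 1
    table = npio.read_table(metrics_csv)
    config = RunConfig(seed=0)
    comparison, strata = compare_metrics(table)
    npio.write_table(comparison, OUT / "comparison.csv", config)
    npio.write_table(strata, OUT / "incision_by_group.csv", config)
    report = _report_text(comparison, strata, config)
    (OUT / "report.txt").write_text(report)
    print(report)
    return 0


if __name__ == "__main__":
    sys.exit(main())
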