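#!/usr/bin/env python
"""Score every simulated drawing set against the projected tumor silhouette.

Reads the annotation JSONs written by 02_simulate_cohort.py, computes the
seven accuracy metrics per participant and assessment, and writes the
metric table to results/metrics.csv. Prints the cohort means so the
calibration against the reference summaries is visible at a glance.
"""

import sys
from pathlib import Path

from neuroplan import io as npio
from neuroplan import metrics as m
from neuroplan import phantom as ph
from neuroplan.io import RunConfig

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    model = ph.build_phantom()
    silhouette = model.silhouette()
    ann_dir = OUT / "cohort" / "annotations"
    if not ann_dir.is_dir():
        print("run 02_simulate_cohort.py first", file=sys.stderr)
        return 1
    manifest = npio.read_table(OUT / "cohort" / "cohort.csv")
    rows = []
    for _, entry in manifest.iterrows():
        ann = npio.read_annotation(OUT / "cohort" / entry["file"])
        res = m.assess(ann, silhouette)
        rows.append(
            {
                "participant_id": entry["participant_id"],
                "group": entry["group"],
                "assessment": entry["assessment"],
                **res.as_row(),
            }
        )
    import pandas as pd

    table = pd.DataFrame(rows)
    npio.write_table(table, OUT / "metrics.csv", RunConfig(seed=0))
    print(f"assessed {len(table)} drawing sets -> {OUT / 'metrics.csv'}")
    cols = ["percent_coverage_pct", "excess_mm2", "painted_area_mm2",
            "incision_deviation_mm", "margin_deviation_sum_mm"]
    print(table.groupby("assessment")[cols].mean().round(1).T)
    return 0


if __name__ == "__main__":
    sys.exit(main())
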