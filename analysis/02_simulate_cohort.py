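#!/usr/bin/env python
"""Simulate the study cohort: 38 participants (14 residents, 24 interns),
each drawing a tumor projection, incisions and a craniotomy twice — once
after MRI-style planning (AA1) and once after 3D-model planning (AA2).

Writes one annotation JSON per drawing set plus a manifest under
results/cohort/. Deterministic under the seed recorded in the manifest.
"""

import sys
from pathlib import Path

from neuroplan import phantom as ph
from neuroplan.io import RunConfig
from neuroplan.pipeline import simulate_cohort_artifacts

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> int:
    model = ph.build_phantom()
    config = RunConfig(seed=SEED)
    records = simulate_cohort_artifacts(model, OUT / "cohort", config)
    n_res = sum(r.group == "resident" for r in records)
    print(f"simulated {len(records)} participants ({n_res} residents, "
          f"{len(records) - n_res} interns), seed {SEED}")
    print(f"annotations in {OUT / 'cohort' / 'annotations'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
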