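#!/usr/bin/env python
"""Generate the synthetic two-arm chip study used by the calibration and
hypothesis-testing scripts.

Ground truth is H2 (hyperglycemia plus a strong time-driven diabetogenic
factor); one hyperglycemic and one normoglycemic arm, four replicate
circuits, 10% multiplicative assay noise, GTT windows on days 1, 7
and 13 (no insulin spike yet -- the day-13 dose is chosen later by the
design script).  Writes the pooled mean/SEM table; the sealed truth
stays out of the interchange file by construction.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, default_params  # noqa: E402

from gluchip.io import write_gtt_table
from gluchip.synth import Condition, StudyDesign, generate_gtt_study


def main():
    truth = default_params("H2")
    design = StudyDesign(
        conditions=(Condition(11.0, "high"), Condition(5.5, "high")),
        n_circuits=4,
        gtt_days=(1, 7, 13),
        spike_nM=None,
        noise_cv=0.10,
        seed=SEED,
    )
    study = generate_gtt_study(truth, design)
    out = RESULTS / "synthetic_study.csv"
    write_gtt_table(study.datasets, out)
    n = sum(ds.n_points for ds in study.datasets)
    print(f"wrote {out}: {len(study.datasets)} conditions, {n} pooled data points")
    for ds in study.datasets:
        glu = ds.table[ds.table.signal == "glucose"]
        print(f"  {ds.condition}: day-1 GTT glucose "
              f"{glu[glu.gtt_window == 'day1']['mean'].round(2).tolist()} mmol/L")


if __name__ == "__main__":
    main()
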