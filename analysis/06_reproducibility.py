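#!/usr/bin/env python
"""Reproducibility statistics on synthetic endpoint matrices.

Generates circuit x timepoint endpoint matrices under three known
variance structures (residual-dominated; circuit-offset-dominated;
strong shared time trend), computes max CV and ICC(2,1) per matrix with
circuits as judges and timepoints as targets, classifies each as
Excellent / Acceptable / Poor, and summarizes per scenario.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED  # noqa: E402

from gluchip.repro import classify_reproducibility, icc2, max_cv
from gluchip.synth import EndpointDesign, generate_endpoint_matrix

SCENARIOS = {
    "residual-only": ({"residual": 1.0}, 0.0),
    "circuit-offsets": ({"circuit": 2.0, "residual": 0.3}, 0.0),
    "shared-time-trend": ({"circuit": 0.1, "residual": 0.1}, 3.0),
}


def main():
    rows = []
    for name, (components, trend) in SCENARIOS.items():
        for rep in range(25):
            mats = generate_endpoint_matrix(
                components,
                EndpointDesign(n_labs=1, n_studies_per_lab=1, n_circuits=4,
                               n_timepoints=7, trend_amplitude=trend,
                               seed=SEED + 100 * rep),
            )
            m = mats[0]
            cv, icc = max_cv(m), icc2(m)
            rows.append({"scenario": name, "rep": rep, "max_cv_percent": cv,
                         "icc2": icc, "status": classify_reproducibility(cv, icc)})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "reproducibility.csv", index=False)
    summary = df.groupby("scenario").agg(
        median_max_cv=("max_cv_percent", "median"),
        median_icc=("icc2", "median"),
        excellent=("status", lambda s: (s == "Excellent").mean()),
        poor=("status", lambda s: (s == "Poor").mean()),
    )
    print(summary.round(3).to_string())
    print("\nShared structure across circuits drives ICC up; circuit offsets and")
    print("residual noise drive it down -- the classification tracks that.")


if __name__ == "__main__":
    main()
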