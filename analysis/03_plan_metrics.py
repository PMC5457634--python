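#!/usr/bin/env python
"""Per-variant plan-metric summary and planning-constraint pass rates.

Produces the mean +/- sd table of HI, DHD, CN, cord D1cc, lung V20Gy/V5Gy/MLD
and mean oesophagus dose for the static technique and each arc collimator
variant, and the percentage of plans meeting the lung, cord and oesophagus
restrictions.  Writes results/plan_summary.csv and results/constraint_pass.csv.
"""

from pathlib import Path

import pandas as pd

from arcdose.cohort_stats import cohort_report

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = pd.read_csv(ROOT / "cohort" / "cohort.csv", index_col=0)
    report = cohort_report(cohort)
    report["summary"].to_csv(ROOT / "plan_summary.csv")
    report["constraints"].to_csv(ROOT / "constraint_pass.csv")
    report["ranks"].to_csv(ROOT / "collimator_ranks.csv")
    print("mean +/- sd per variant:")
    print(report["summary"].round(3).to_string())
    print("\nconstraint pass rates (%):")
    print(report["constraints"].round(0).to_string())
    print("\nbest-variant counts across arc collimator settings:")
    print(report["ranks"].to_string())


if __name__ == "__main__":
    main()
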