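"""Ingest the cohort, apply the retention QC, and compute repertoire metrics.

Reads scratch/cohort/, writes sample_metrics.csv, course_metrics.csv and
qc_exclusions.csv under results/, and reports how many samples and paired
courses survive QC.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_DIR, QC, RESULTS_DIR

from tcrdyn.io import pair_timepoints, qc_filter, read_clonotype_table
from tcrdyn.metrics import course_metrics_table, sample_metrics_table


def main() -> None:
    reps = [
        read_clonotype_table(p, "simple_csv")
        for p in sorted(COHORT_DIR.glob("*.csv"))
        if p.name != "clinical.csv"
    ]
    qc_results, excl = {}, []
    for rep in reps:
        ok, reasons = qc_filter(rep, QC)
        qc_results[rep.sample_id] = ok
        if not ok:
            excl.append({"sample_id": rep.sample_id, "reasons": "; ".join(reasons)})

    passing = [r for r in reps if qc_results[r.sample_id]]
    courses = pair_timepoints(reps, qc_results)
    samples = sample_metrics_table(passing)
    course = course_metrics_table(courses)

    RESULTS_DIR.mkdir(exist_ok=True)
    samples.to_csv(RESULTS_DIR / "sample_metrics.csv", index=False)
    course.to_csv(RESULTS_DIR / "course_metrics.csv", index=False)
    pd.DataFrame(excl, columns=["sample_id", "reasons"]).to_csv(RESULTS_DIR / "qc_exclusions.csv", index=False)

    paired = course["rcl"].notna()
    print(f"{len(reps)} samples read; {len(passing)} passed QC, {len(excl)} excluded")
    print(f"{paired.sum()} of {len(course)} patients have both timepoints after QC")
    print(f"median baseline clonality: {samples.loc[samples.timepoint == 'C1D1', 'clonality'].median():.4f}")
    print(f"median TCF:                {samples['tcf'].median():.4f}")
    inc = (course.loc[paired, 'rcl'] >= 1).sum()
    print(f"patients with increased clonality (RCL >= 1): {inc} / {int(paired.sum())}")


if __name__ == "__main__":
    main()
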