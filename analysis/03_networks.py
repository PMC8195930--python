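"""Build per-patient CDR3 similarity networks and split at the median diameter.

Reads scratch/cohort/, writes network_summary.csv under results/, and
reports the cohort median diameter and the high/low split sizes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_DIR, QC, RESULTS_DIR

from tcrdyn.io import pair_timepoints, qc_filter, read_clonotype_table
from tcrdyn.network import build_network, network_summary_table


def main() -> None:
    reps = [
        read_clonotype_table(p, "simple_csv")
        for p in sorted(COHORT_DIR.glob("*.csv"))
        if p.name != "clinical.csv"
    ]
    qc_results = {r.sample_id: qc_filter(r, QC)[0] for r in reps}
    courses = pair_timepoints(reps, qc_results)

    graphs = [build_network(c) for c in courses if c.baseline is not None or c.post is not None]
    summary = network_summary_table(graphs)
    RESULTS_DIR.mkdir(exist_ok=True)
    summary.to_csv(RESULTS_DIR / "network_summary.csv", index=False)

    med = summary["diameter"].median()
    counts = summary["diameter_group"].value_counts()
    print(f"networks built for {len(graphs)} patients")
    print(f"median nodes/patient: {summary['n_nodes'].median():.0f}, median edges: {summary['n_edges'].median():.0f}")
    print(f"median diameter: {med:.1f} (edges); split high > {med:.1f}: "
          f"{counts.get('high', 0)} high / {counts.get('low', 0)} low")


if __name__ == "__main__":
    main()
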