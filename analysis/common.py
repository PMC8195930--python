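"""Shared settings for the analysis drivers.

The cohort is simulated at a reduced per-sample depth (150 clones, ~60k
reads) so the whole analysis runs in seconds; the QC thresholds are scaled
to the same proportions as the full-depth retention filter. Three baseline
samples are generated below the unique-clone threshold so the QC stage has
real work to do.
"""

from pathlib import Path

from tcrdyn.simulate import SimulationParams
from tcrdyn.types import QCThresholds

ROOT = Path(__file__).resolve().parent.parent
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS_DIR = ROOT / "results"

SEED = 20251002

SIM = SimulationParams(
    n_patients=71,
    n_clones_per_sample=150,
    read_depth=60_000,
    n_qc_fail=3,
    qc_fail_clone_count=100,
    seed=SEED,
)

QC = QCThresholds(
    min_unique_clones=150,
    min_read_depth=48_000,
    min_productive_fraction=0.40,
)
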