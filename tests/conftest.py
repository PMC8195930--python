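from __future__ import annotations

import numpy as np
import pytest

from tcrdyn.types import ClonotypeRecord, PatientCourse, Repertoire, Timepoint


def make_repertoire(
    clones,
    sample_id="S1",
    patient_id="P1",
    timepoint=Timepoint.C1D1,
    total_reads=None,
):
    """Build a Repertoire from (nt, aa, count[, productive]) tuples.

    Frequencies are computed over productive records, as ingestion would.
    """
    norm = []
    for c in clones:
        nt, aa, count = c[0], c[1], c[2]
        productive = c[3] if len(c) > 3 else True
        norm.append((nt, aa, count, productive))
    prod_total = sum(count for _, _, count, productive in norm if productive)
    records = [
        ClonotypeRecord(
            nt_cdr3=nt,
            aa_cdr3=aa,
            read_count=count,
            frequency=(count / prod_total) if productive else 0.0,
            productive=productive,
        )
        for nt, aa, count, productive in norm
    ]
    all_total = sum(count for _, _, count, _ in norm)
    return Repertoire(
        sample_id=sample_id,
        patient_id=patient_id,
        timepoint=Timepoint(timepoint),
        records=records,
        total_reads=total_reads if total_reads is not None else all_total,
        productive_fraction=prod_total / all_total,
        n_unique_clones=len(records),
    )


def make_course(baseline_clones, post_clones, patient_id="P1"):
    return PatientCourse(
        patient_id=patient_id,
        baseline=make_repertoire(
            baseline_clones, sample_id=f"{patient_id}_C1D1", patient_id=patient_id, timepoint=Timepoint.C1D1
        )
        if baseline_clones is not None
        else None,
        post=make_repertoire(
            post_clones, sample_id=f"{patient_id}_C1D15", patient_id=patient_id, timepoint=Timepoint.C1D15
        )
        if post_clones is not None
        else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)


def random_aa(rng, lo=5, hi=16):
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    length = int(rng.integers(lo, hi + 1))
    return "".join(alphabet[rng.integers(0, 20, size=length)])
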