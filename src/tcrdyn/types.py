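"""Core domain containers for TCR-beta repertoire analysis.

A *clone* (clonotype) is a unique nucleotide-level CDR3 rearrangement;
several clones may translate to the same amino-acid CDR3, which is the
basis of the convergence metrics downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "Timepoint",
    "ClonotypeRecord",
    "Repertoire",
    "QCThresholds",
    "PatientCourse",
]


class Timepoint(str, enum.Enum):
    """Sampling timepoint: pre-infusion baseline (C1D1) or day 15 (C1D15)."""

    C1D1 = "C1D1"
    C1D15 = "C1D15"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class ClonotypeRecord:
    """One nucleotide-level clone with its amino-acid CDR3 and abundance.

    ``frequency`` is the clone's share of *productive* reads in its sample;
    unproductive records (stop codon / frameshift in the CDR3) carry
    frequency 0 and are retained only for the productive-fraction QC.
    """

    nt_cdr3: str
    aa_cdr3: str
    read_count: int
    frequency: float = 0.0
    v_gene: str | None = None
    j_gene: str | None = None
    productive: bool = True

    def __post_init__(self) -> None:
        if not self.nt_cdr3:
            raise ValueError("nt_cdr3 must be non-empty")
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError("frequency must lie in [0, 1]")
        if self.productive and "*" in self.aa_cdr3:
            raise ValueError("productive record must not contain a stop symbol in aa_cdr3")


@dataclass
class Repertoire:
    """One sample (patient x timepoint): its clones plus sample-level QC fields.

    ``total_reads`` is the library read depth; when the clonotype table does
    not carry it, it defaults to the sum of read counts over all records.
    """

    sample_id: str
    patient_id: str
    timepoint: Timepoint
    records: list[ClonotypeRecord] = field(default_factory=list)
    total_reads: int = 0
    productive_fraction: float = 0.0
    n_unique_clones: int = 0

    def productive_records(self) -> list[ClonotypeRecord]:
        return [r for r in self.records if r.productive]

    def productive_frequencies(self) -> list[float]:
        return [r.frequency for r in self.productive_records()]


@dataclass(frozen=True)
class QCThresholds:
    """Sample-level retention thresholds (all comparisons are inclusive >=)."""

    min_unique_clones: int = 1000
    min_read_depth: int = 800_000
    min_productive_fraction: float = 0.40

    def __post_init__(self) -> None:
        if self.min_unique_clones < 0 or self.min_read_depth < 0 or self.min_productive_fraction < 0:
            raise ValueError("QC thresholds must be >= 0")


@dataclass
class PatientCourse:
    """Paired baseline (C1D1) / post (C1D15) repertoires for one patient.

    ``has_both`` is true only when both timepoints are present *and* both
    passed QC; single-timepoint courses are kept for baseline-only analyses.
    """

    patient_id: str
    baseline: Repertoire | None = None
    post: Repertoire | None = None

    @property
    def has_both(self) -> bool:
        return self.baseline is not None and self.post is not None
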