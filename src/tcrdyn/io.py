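"""Reading/writing clonotype and clinical tables, sample QC, timepoint pairing.

Two table dialects are supported:

* ``airr_tsv`` — tab-separated with AIRR Rearrangement column names
  (``junction``, ``junction_aa``, ``duplicate_count``, ``v_call``,
  ``j_call``, ``productive``);
* ``simple_csv`` — comma-separated with ``nt_cdr3``, ``aa_cdr3``,
  ``read_count`` and optional ``productive`` / ``v_gene`` / ``j_gene``.

Clone identity is the nucleotide CDR3: rows sharing ``nt_cdr3`` are
aggregated by summing read counts on ingestion. Clone frequencies are
recomputed over productive records so they always sum to one.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .errors import (
    AmbiguousSampleError,
    ClonotypeFormatError,
    DegenerateSampleError,
    ValidationError,
)
from .types import ClonotypeRecord, PatientCourse, QCThresholds, Repertoire, Timepoint

__all__ = [
    "read_clonotype_table",
    "write_clonotype_table",
    "qc_filter",
    "pair_timepoints",
    "read_clinical_table",
    "CLINICAL_COVARIATES",
]

_AIRR_COLS = ["junction", "junction_aa", "duplicate_count", "v_call", "j_call", "productive"]
_SIMPLE_MANDATORY = ["nt_cdr3", "aa_cdr3", "read_count"]

#: Binary covariates of the clinical table, in model order. ``sex`` and
#: ``smoking`` are recoded to ``male_sex`` / ``ever_smoker`` internally.
CLINICAL_COVARIATES = [
    "male_sex",
    "age_ge_65",
    "squamous",
    "pdl1_low_neg",
    "ecog_1",
    "ever_smoker",
    "prior_line",
    "liver_mets",
]


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"t", "true", "1", "yes"}:
        return True
    if s in {"f", "false", "0", "no"}:
        return False
    raise ClonotypeFormatError(f"cannot parse boolean value {value!r} in 'productive' column")


def _infer_metadata(path: Path) -> tuple[str, str, Timepoint]:
    """Infer (sample_id, patient_id, timepoint) from a ``<patient>_<timepoint>`` stem."""
    stem = path.stem
    sample_id = stem
    patient_id = stem
    timepoint = Timepoint.C1D1
    if "_" in stem:
        maybe_patient, _, maybe_tp = stem.rpartition("_")
        try:
            timepoint = Timepoint(maybe_tp)
            patient_id = maybe_patient
        except ValueError:
            pass
    return sample_id, patient_id, timepoint


def read_clonotype_table(
    path: str | os.PathLike,
    dialect: str = "simple_csv",
    *,
    sample_id: str | None = None,
    patient_id: str | None = None,
    timepoint: Timepoint | str | None = None,
) -> Repertoire:
    """Read one clonotype table into a :class:`Repertoire`.

    Rows with identical ``nt_cdr3`` are aggregated (read counts summed);
    frequencies are recomputed as read_count / sum of productive read
    counts. Sample metadata not passed explicitly is inferred from the
    filename stem (``<patient>_<timepoint>``).

    Raises
    ------
    ClonotypeFormatError
        If a mandatory column for the dialect is missing.
    DegenerateSampleError
        If the table carries zero productive reads.
    """
    path = Path(path)
    if dialect == "airr_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        mandatory = _AIRR_COLS
    elif dialect == "simple_csv":
        df = pd.read_csv(path, dtype=str)
        mandatory = _SIMPLE_MANDATORY
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    for col in mandatory:
        if col not in df.columns:
            raise ClonotypeFormatError(f"{path}: missing mandatory column '{col}' for dialect {dialect}")

    if dialect == "airr_tsv":
        df = df.rename(
            columns={
                "junction": "nt_cdr3",
                "junction_aa": "aa_cdr3",
                "duplicate_count": "read_count",
                "v_call": "v_gene",
                "j_call": "j_gene",
            }
        )

    df["read_count"] = df["read_count"].astype(int)
    if "productive" in df.columns:
        df["productive"] = df["productive"].map(_parse_bool)
    else:
        df["productive"] = True
    for opt in ("v_gene", "j_gene"):
        if opt not in df.columns:
            df[opt] = None
    df["aa_cdr3"] = df["aa_cdr3"].fillna("")

    # Aggregate nucleotide-identical rows; non-count fields come from the first row.
    agg = df.groupby("nt_cdr3", sort=False).agg(
        aa_cdr3=("aa_cdr3", "first"),
        read_count=("read_count", "sum"),
        v_gene=("v_gene", "first"),
        j_gene=("j_gene", "first"),
        productive=("productive", "first"),
    )

    total_reads = int(df["read_count"].sum())
    productive_reads = int(agg.loc[agg["productive"], "read_count"].sum())
    if productive_reads == 0:
        raise DegenerateSampleError(f"{path}: sample has zero productive reads")

    records = []
    for nt, row in agg.iterrows():
        count = int(row["read_count"])
        freq = count / productive_reads if row["productive"] else 0.0
        records.append(
            ClonotypeRecord(
                nt_cdr3=str(nt),
                aa_cdr3=str(row["aa_cdr3"]),
                read_count=count,
                frequency=freq,
                v_gene=row["v_gene"] if pd.notna(row["v_gene"]) else None,
                j_gene=row["j_gene"] if pd.notna(row["j_gene"]) else None,
                productive=bool(row["productive"]),
            )
        )

    inferred = _infer_metadata(path)
    tp = timepoint if timepoint is not None else inferred[2]
    return Repertoire(
        sample_id=sample_id if sample_id is not None else inferred[0],
        patient_id=patient_id if patient_id is not None else inferred[1],
        timepoint=Timepoint(tp),
        records=records,
        total_reads=total_reads,
        productive_fraction=productive_reads / total_reads,
        n_unique_clones=len(records),
    )


def write_clonotype_table(repertoire: Repertoire, path: str | os.PathLike, dialect: str = "simple_csv") -> None:
    """Write a repertoire so that re-reading reproduces all fields exactly."""
    path = Path(path)
    rows = [
        {
            "nt_cdr3": r.nt_cdr3,
            "aa_cdr3": r.aa_cdr3,
            "read_count": r.read_count,
            "v_gene": r.v_gene,
            "j_gene": r.j_gene,
            "productive": "T" if r.productive else "F",
        }
        for r in repertoire.records
    ]
    df = pd.DataFrame(rows, columns=["nt_cdr3", "aa_cdr3", "read_count", "v_gene", "j_gene", "productive"])
    try:
        if dialect == "simple_csv":
            df.to_csv(path, index=False)
        elif dialect == "airr_tsv":
            df = df.rename(
                columns={
                    "nt_cdr3": "junction",
                    "aa_cdr3": "junction_aa",
                    "read_count": "duplicate_count",
                    "v_gene": "v_call",
                    "j_gene": "j_call",
                }
            )
            df.to_csv(path, sep="\t", index=False)
        else:
            raise ValidationError(f"unknown dialect {dialect!r}")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed to write clonotype table to {path}: {exc}") from exc


def qc_filter(repertoire: Repertoire, thresholds: QCThresholds = QCThresholds()) -> tuple[bool, list[str]]:
    """Apply the sample-retention filter; returns (pass, reasons-for-failure).

    A sample is retained iff unique clones, read depth, and the productive
    read fraction all meet their thresholds (inclusive).
    """
    reasons = []
    if repertoire.n_unique_clones < thresholds.min_unique_clones:
        reasons.append(
            f"unique clones {repertoire.n_unique_clones} < {thresholds.min_unique_clones}"
        )
    if repertoire.total_reads < thresholds.min_read_depth:
        reasons.append(f"read depth {repertoire.total_reads} < {thresholds.min_read_depth}")
    if repertoire.productive_fraction < thresholds.min_productive_fraction:
        reasons.append(
            f"productive fraction {repertoire.productive_fraction:.3f} < {thresholds.min_productive_fraction}"
        )
    return (len(reasons) == 0, reasons)


def pair_timepoints(
    samples: list[Repertoire], qc_results: dict[str, bool]
) -> list[PatientCourse]:
    """Group QC-passing samples into per-patient baseline/post courses.

    Samples that failed QC are dropped from the course (a course with a
    single passing timepoint is retained for baseline-only analyses).

    Raises
    ------
    AmbiguousSampleError
        If two samples share the same (patient, timepoint).
    """
    seen: dict[tuple[str, Timepoint], str] = {}
    for s in samples:
        key = (s.patient_id, s.timepoint)
        if key in seen:
            raise AmbiguousSampleError(
                f"duplicate sample for patient {s.patient_id!r} at {s.timepoint}: "
                f"{seen[key]!r} and {s.sample_id!r}"
            )
        seen[key] = s.sample_id

    courses: dict[str, PatientCourse] = {}
    for s in samples:
        course = courses.setdefault(s.patient_id, PatientCourse(patient_id=s.patient_id))
        if not qc_results.get(s.sample_id, False):
            continue
        if s.timepoint == Timepoint.C1D1:
            course.baseline = s
        else:
            course.post = s
    return list(courses.values())


def read_clinical_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the patient-level clinical CSV into an analysis-ready frame.

    Expected columns: ``patient_id``, ``os_months``, ``event`` plus the
    binary covariates ``sex`` (1 = male), ``age_ge_65``, ``squamous``,
    ``pdl1_low_neg``, ``ecog_1``, ``smoking`` (1 = ever-smoker),
    ``prior_line``, ``liver_mets``. ``sex``/``smoking`` are recoded to
    ``male_sex``/``ever_smoker``.
    """
    df = pd.read_csv(path)
    for col in ("patient_id", "os_months", "event"):
        if col not in df.columns:
            raise ClonotypeFormatError(f"{path}: missing mandatory clinical column '{col}'")
    df = df.rename(columns={"sex": "male_sex", "smoking": "ever_smoker"})
    df["patient_id"] = df["patient_id"].astype(str)
    df["os_months"] = df["os_months"].astype(float)
    if (df["os_months"] <= 0).any():
        raise ValidationError(f"{path}: os_months must be > 0")
    df["event"] = df["event"].astype(int)
    return df
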