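"""Repertoire diversity and convergence metrics, and their pre/post ratios.

Clonality is one minus the normalized Shannon entropy of productive clone
frequencies,

    clonality = 1 - H / ln(R),    H = -sum_i p_i ln p_i,

where R is the number of unique productive nucleotide clones. It is 0 for
a perfectly even repertoire and approaches 1 as a single clone dominates.

TCR convergence frequency (TCF) is the aggregate frequency of clones whose
amino-acid CDR3 is shared by at least one other (nucleotide-distinct)
clone. Treatment dynamics are summarized by the post/baseline ratios RCL
(relative clonality) and RTCF, dichotomized at 1 (a ratio of exactly 1
counts as "increased").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .types import PatientCourse, Repertoire

__all__ = [
    "RepertoireMetrics",
    "CourseMetrics",
    "shannon_entropy",
    "clonality",
    "convergence_frequency",
    "relative_metric",
    "compute_repertoire_metrics",
    "compute_course_metrics",
    "assign_dynamic_groups",
    "sample_metrics_table",
    "course_metrics_table",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class RepertoireMetrics:
    """Per-sample summary: richness R, entropy H (nats), clonality, TCF."""

    richness: int
    entropy_nats: float
    clonality: float
    tcf: float


@dataclass(frozen=True)
class CourseMetrics:
    """Per-patient treatment dynamics: RCL, RTCF and the derived group flags."""

    rcl: float
    rtcf: float | None

    @property
    def increased_clonality(self) -> bool:
        return self.rcl >= 1.0

    @property
    def increased_tcf(self) -> bool | None:
        if self.rtcf is None:
            return None
        return self.rtcf >= 1.0

    @property
    def dual_increase(self) -> bool | None:
        if self.rtcf is None:
            return None
        return self.increased_clonality and self.rtcf >= 1.0


def shannon_entropy(frequencies) -> float:
    """Shannon entropy -sum p ln p in nats; exact zeros are dropped first."""
    p = np.asarray(frequencies, dtype=float)
    p = p[p > 0]
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValidationError(f"frequencies sum to {p.sum()!r}, not 1")
    return float(-(p * np.log(p)).sum())


def clonality(repertoire: Repertoire | list[float]) -> float:
    """Normalized-entropy clonality 1 - H/ln(R) of productive clone frequencies.

    Accepts a :class:`Repertoire` or a bare frequency vector. Undefined for
    repertoires with fewer than two unique productive clones (ln R = 0).
    """
    if isinstance(repertoire, Repertoire):
        freqs = repertoire.productive_frequencies()
    else:
        freqs = list(repertoire)
    r = len(freqs)
    if r <= 1:
        raise UndefinedMetricError(f"clonality undefined for {r} unique productive clone(s)")
    return 1.0 - shannon_entropy(freqs) / math.log(r)


def convergence_frequency(repertoire: Repertoire) -> float:
    """Aggregate frequency of productive clones in amino-acid groups of size >= 2.

    Clones with a missing amino-acid CDR3 are excluded from the grouping.
    """
    groups: dict[str, list[float]] = {}
    for rec in repertoire.productive_records():
        if not rec.aa_cdr3:
            continue
        groups.setdefault(rec.aa_cdr3, []).append(rec.frequency)
    return float(sum(sum(v) for v in groups.values() if len(v) >= 2))


def relative_metric(baseline_value: float, post_value: float) -> float:
    """Post/baseline ratio (RCL or RTCF); undefined when the baseline is 0."""
    if baseline_value == 0:
        raise UndefinedMetricError("relative metric undefined for baseline value 0")
    return post_value / baseline_value


def compute_repertoire_metrics(repertoire: Repertoire) -> RepertoireMetrics:
    freqs = repertoire.productive_frequencies()
    return RepertoireMetrics(
        richness=len(freqs),
        entropy_nats=shannon_entropy(freqs),
        clonality=clonality(repertoire),
        tcf=convergence_frequency(repertoire),
    )


def compute_course_metrics(course: PatientCourse) -> CourseMetrics | None:
    """RCL/RTCF for a paired course; None when either timepoint is missing.

    RTCF is None when the baseline TCF is 0 (the ratio is undefined); the
    patient is then excluded from TCF-based groupings downstream.
    """
    if not course.has_both:
        return None
    base = compute_repertoire_metrics(course.baseline)
    post = compute_repertoire_metrics(course.post)
    rcl = relative_metric(base.clonality, post.clonality)
    rtcf = relative_metric(base.tcf, post.tcf) if base.tcf > 0 else None
    return CourseMetrics(rcl=rcl, rtcf=rtcf)


def assign_dynamic_groups(cm: CourseMetrics) -> dict[str, str | None]:
    """Dichotomous group labels from the ratios (boundary 1 is 'increased')."""
    tcf_group = None if cm.rtcf is None else ("increased" if cm.rtcf >= 1.0 else "decreased")
    dual = None
    if cm.rtcf is not None:
        dual = "dual-increase" if (cm.rcl >= 1.0 and cm.rtcf >= 1.0) else "rest"
    return {
        "clonality_group": "increased" if cm.rcl >= 1.0 else "decreased",
        "tcf_group": tcf_group,
        "dual_group": dual,
    }


def sample_metrics_table(repertoires: list[Repertoire]) -> pd.DataFrame:
    """Per-sample metrics CSV shape: one row per QC-passing sample."""
    rows = []
    for rep in repertoires:
        m = compute_repertoire_metrics(rep)
        rows.append(
            {
                "sample_id": rep.sample_id,
                "patient_id": rep.patient_id,
                "timepoint": rep.timepoint.value,
                "richness": m.richness,
                "entropy_nats": m.entropy_nats,
                "clonality": m.clonality,
                "tcf": m.tcf,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "patient_id", "timepoint", "richness", "entropy_nats", "clonality", "tcf"],
    )


def course_metrics_table(courses: list[PatientCourse]) -> pd.DataFrame:
    """Per-patient course CSV shape; patients without a valid pair get NaN ratios."""
    rows = []
    for course in courses:
        cm = compute_course_metrics(course)
        if cm is None:
            rows.append(
                {
                    "patient_id": course.patient_id,
                    "rcl": np.nan,
                    "rtcf": np.nan,
                    "clonality_group": None,
                    "tcf_group": None,
                    "dual_group": None,
                }
            )
            continue
        groups = assign_dynamic_groups(cm)
        rows.append(
            {
                "patient_id": course.patient_id,
                "rcl": cm.rcl,
                "rtcf": np.nan if cm.rtcf is None else cm.rtcf,
                **groups,
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "rcl", "rtcf", "clonality_group", "tcf_group", "dual_group"]
    )
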