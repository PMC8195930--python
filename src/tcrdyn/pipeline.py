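"""End-to-end orchestration: ingest -> QC -> metrics -> networks -> survival.

The pipeline mirrors a two-timepoint repertoire study: samples failing the
retention QC are logged and dropped, paired courses yield relative
clonality / convergence ratios and their dichotomous groups, per-patient
similarity networks are summarized by diameter and split at the cohort
median, and every grouping plus the clinical covariates feeds
Kaplan-Meier / log-rank summaries and univariable + backward-selected
multivariable Cox models.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from . import metrics as rmetrics
from . import network as rnet
from . import survival as rsurv
from .errors import ValidationError
from .simulate import SimulationParams, simulate_cohort
from .types import QCThresholds, Repertoire, Timepoint

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "summarize_baseline", "write_report"]

_COX_COVARIATES = [
    "male_sex",
    "age_ge_65",
    "squamous",
    "pdl1_low_neg",
    "ecog_1",
    "ever_smoker",
    "prior_line",
    "liver_mets",
]


@dataclass
class PipelineConfig:
    """Pipeline configuration; exactly one of simulate/real-input mode is active.

    Real-input mode reads per-sample clonotype tables named
    ``<patient>_<timepoint>.<ext>`` from ``input_dir`` plus ``clinical_csv``;
    simulate mode generates a synthetic cohort from ``sim`` (seeded by
    ``seed``).
    """

    mode: str = "simulate"  # {"simulate", "real"}
    input_dir: str | None = None
    clinical_csv: str | None = None
    dialect: str = "simple_csv"
    sim: SimulationParams = field(default_factory=SimulationParams)
    qc: QCThresholds = field(default_factory=QCThresholds)
    diameter_units: str = "edges"  # {"edges", "vertices"}
    ties: str = "efron"
    p_keep: float = 0.2
    network_top_n: int | None = None
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in {"simulate", "real"}:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "real" and (self.input_dir is None or self.clinical_csv is None):
            raise ValidationError("real mode requires input_dir and clinical_csv")
        if self.diameter_units not in {"edges", "vertices"}:
            raise ValidationError(f"unknown diameter units {self.diameter_units!r}")

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["sim"]["aa_length_range"] = list(d["sim"]["aa_length_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("sim", {})
        sim["aa_length_range"] = tuple(sim.get("aa_length_range", (8, 20)))
        qc = d.pop("qc", {})
        return cls(sim=SimulationParams(**sim), qc=QCThresholds(**qc), **d)


@dataclass
class AnalysisReport:
    """All pipeline outputs plus the QC-exclusion and run logs."""

    sample_metrics: pd.DataFrame
    course_metrics: pd.DataFrame
    network_summary: pd.DataFrame
    km_summaries: pd.DataFrame
    cox_table: pd.DataFrame
    clonality_association: pd.DataFrame
    qc_exclusions: pd.DataFrame
    run_log: dict


def _ingest_real(config: PipelineConfig) -> tuple[list[Repertoire], pd.DataFrame, list[str]]:
    notes = []
    reps = []
    ext = "tsv" if config.dialect == "airr_tsv" else "csv"
    for path in sorted(Path(config.input_dir).glob(f"*.{ext}")):
        if path.name == "clinical.csv":
            continue
        stem = path.stem
        tp_token = stem.rpartition("_")[2]
        if tp_token not in {t.value for t in Timepoint}:
            notes.append(f"ignored {path.name}: unrecognized timepoint token {tp_token!r}")
            continue
        reps.append(rio.read_clonotype_table(path, config.dialect))
    clinical = rio.read_clinical_table(config.clinical_csv)
    return reps, clinical, notes


def _km_grouping_rows(surv: pd.DataFrame, column: str, grouping: str) -> list[dict]:
    rows = []
    sub = surv.dropna(subset=[column])
    groups = sorted(sub[column].unique())
    logrank_p = np.nan
    if len(groups) >= 2:
        _, logrank_p = rsurv.logrank_test(sub[column].to_numpy(), sub)
    for g in groups:
        gdf = sub[sub[column] == g]
        curve = rsurv.km_estimate(gdf)
        rows.append(
            {
                "grouping": grouping,
                "group": g,
                "n": curve.n,
                "events": curve.n_events,
                "median_os": rsurv.NOT_REACHED if curve.median is None else curve.median,
                "logrank_p": logrank_p,
            }
        )
    return rows


def _cox_table(surv: pd.DataFrame, ties: str, p_keep: float) -> pd.DataFrame:
    """Table-2-shaped output: univariable column per term, multivariable final model."""
    uni_terms = _COX_COVARIATES + ["baseline_clonality", "rcl", "increased_clonality"]
    rows = []
    for term in uni_terms:
        sub = surv.dropna(subset=[term])
        entry = {"term": term, "uni_hr": np.nan, "uni_ci_lower": np.nan, "uni_ci_upper": np.nan,
                 "uni_p": np.nan, "uni_n": len(sub), "note": ""}
        try:
            res = rsurv.cox_fit(sub, [term], ties=ties)
            entry.update(
                uni_hr=res.hr[term], uni_ci_lower=res.ci_lower[term],
                uni_ci_upper=res.ci_upper[term], uni_p=res.p[term],
            )
        except (ValidationError, rsurv.ConvergenceError) as exc:
            entry["note"] = str(exc)
        rows.append(entry)
    table = pd.DataFrame(rows)

    multi_terms = [t for t in _COX_COVARIATES + ["increased_clonality"] if surv[t].dropna().nunique() > 1]
    multi_df = surv.dropna(subset=multi_terms)
    for col in ("multi_hr", "multi_ci_lower", "multi_ci_upper", "multi_p"):
        table[col] = np.nan
    final = None
    if len(multi_df) >= 10 and multi_df["event"].sum() > 0:
        # small cohorts can show monotone likelihood for some terms; drop the
        # diverging term and refit rather than abandoning the multivariable model
        terms_left = list(multi_terms)
        while terms_left:
            try:
                final = rsurv.backward_select(multi_df, terms_left, p_keep=p_keep, ties=ties)
                break
            except rsurv.ConvergenceError as exc:
                diverged = next((t for t in terms_left if f"'{t}'" in str(exc)), None)
                if diverged is None:
                    break
                terms_left.remove(diverged)
                table.loc[table["term"] == diverged, "note"] = "dropped from multivariable model: " + str(exc)
    if final is not None:
        for term in final.terms:
            mask = table["term"] == term
            table.loc[mask, "multi_hr"] = final.hr[term]
            table.loc[mask, "multi_ci_lower"] = final.ci_lower[term]
            table.loc[mask, "multi_ci_upper"] = final.ci_upper[term]
            table.loc[mask, "multi_p"] = final.p[term]
    return table


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute every stage in order; all randomness flows from ``config.seed``."""
    config.validate()
    run_log: dict = {"stages": [], "notes": []}

    # --- ingest -----------------------------------------------------------
    if config.mode == "simulate":
        sim = dataclasses.replace(config.sim, seed=config.seed)
        cohort = simulate_cohort(sim)
        reps, clinical = cohort.repertoires, cohort.clinical
    else:
        reps, clinical, notes = _ingest_real(config)
        run_log["notes"].extend(notes)
    clinical = clinical.rename(columns={"sex": "male_sex", "smoking": "ever_smoker"})
    all_patients = sorted({r.patient_id for r in reps} | set(clinical["patient_id"].astype(str)))
    run_log["stages"].append({"stage": "ingest", "n_samples": len(reps), "n_patients": len(all_patients)})

    # --- QC ---------------------------------------------------------------
    qc_results: dict[str, bool] = {}
    excl_rows = []
    for rep in reps:
        ok, reasons = rio.qc_filter(rep, config.qc)
        qc_results[rep.sample_id] = ok
        if not ok:
            excl_rows.append(
                {"sample_id": rep.sample_id, "patient_id": rep.patient_id,
                 "timepoint": rep.timepoint.value, "reasons": "; ".join(reasons)}
            )
    qc_exclusions = pd.DataFrame(excl_rows, columns=["sample_id", "patient_id", "timepoint", "reasons"])
    passing = [r for r in reps if qc_results[r.sample_id]]
    run_log["stages"].append(
        {"stage": "qc", "n_in": len(reps), "n_pass": len(passing), "n_fail": len(excl_rows)}
    )

    # --- metrics ----------------------------------------------------------
    courses = rio.pair_timepoints(reps, qc_results)
    sample_metrics = rmetrics.sample_metrics_table(passing)
    course_metrics = rmetrics.course_metrics_table(courses)
    run_log["stages"].append(
        {
            "stage": "metrics",
            "n_courses": len(courses),
            "n_paired": int(sum(c.has_both for c in courses)),
        }
    )

    # --- networks ---------------------------------------------------------
    graphs = [
        rnet.build_network(c, top_n=config.network_top_n)
        for c in courses
        if c.baseline is not None or c.post is not None
    ]
    network_summary = rnet.network_summary_table(graphs)
    if config.diameter_units == "vertices" and len(network_summary):
        network_summary["diameter"] = np.where(
            network_summary["n_nodes"] > 0, network_summary["diameter"] + 1, 0
        )
    run_log["stages"].append({"stage": "network", "n_graphs": len(graphs)})

    # --- survival ---------------------------------------------------------
    baseline_cl = (
        sample_metrics[sample_metrics["timepoint"] == Timepoint.C1D1.value]
        .set_index("patient_id")["clonality"]
        .rename("baseline_clonality")
    )
    surv = (
        clinical.assign(patient_id=clinical["patient_id"].astype(str))
        .merge(course_metrics, on="patient_id", how="left")
        .merge(baseline_cl, on="patient_id", how="left")
    )
    if len(network_summary):
        surv = surv.merge(
            network_summary[["patient_id", "diameter_group"]], on="patient_id", how="left"
        )
    else:
        surv["diameter_group"] = None
    surv["increased_clonality"] = np.where(
        surv["rcl"].isna(), np.nan, (surv["rcl"] >= 1.0).astype(float)
    )

    km_rows = []
    for column, grouping in [
        ("clonality_group", "rcl"),
        ("tcf_group", "rtcf"),
        ("dual_group", "dual"),
        ("diameter_group", "diameter"),
    ]:
        if column in surv.columns:
            km_rows.extend(_km_grouping_rows(surv, column, grouping))
    km_summaries = pd.DataFrame(
        km_rows, columns=["grouping", "group", "n", "events", "median_os", "logrank_p"]
    )

    cox_table = _cox_table(surv, config.ties, config.p_keep)

    try:
        clon_assoc = rsurv.covariate_association_with_rcl(surv, _COX_COVARIATES)
    except (ValidationError, rsurv.ConvergenceError) as exc:
        clon_assoc = pd.DataFrame(columns=["term", "log_odds", "odds_ratio", "p", "excluded"])
        run_log["notes"].append(f"clonality association skipped: {exc}")
    run_log["stages"].append(
        {"stage": "survival", "n_patients": int(len(surv)), "n_events": int(surv["event"].sum())}
    )

    # patient conservation: everyone is analyzed or excluded (or both, for
    # patients with one passing and one failing sample)
    analyzed = set(course_metrics["patient_id"]) | set(surv["patient_id"])
    excluded = set(qc_exclusions["patient_id"])
    missing = set(all_patients) - analyzed - excluded
    if missing:
        raise ValidationError(f"patients lost by the pipeline: {sorted(missing)}")
    run_log["conservation"] = {
        "n_input_patients": len(all_patients),
        "n_analyzed": len(analyzed & set(all_patients)),
        "n_with_excluded_sample": len(excluded & set(all_patients)),
    }
    run_log["config"] = {"mode": config.mode, "seed": config.seed, "ties": config.ties,
                         "p_keep": config.p_keep, "diameter_units": config.diameter_units}

    return AnalysisReport(
        sample_metrics=sample_metrics,
        course_metrics=course_metrics,
        network_summary=network_summary,
        km_summaries=km_summaries,
        cox_table=cox_table,
        clonality_association=clon_assoc,
        qc_exclusions=qc_exclusions,
        run_log=run_log,
    )


def summarize_baseline(clinical: pd.DataFrame) -> pd.DataFrame:
    """Frequency (percentage) per binary covariate; median (range) for continuous.

    Percentages are printed to one decimal place.
    """
    known = set(rio.CLINICAL_COVARIATES) | {"sex", "smoking"}
    rows = []
    n = len(clinical)
    for col in clinical.columns:
        if col in ("patient_id", "event"):
            continue
        if col == "os_months":
            rows.append(
                {
                    "characteristic": col,
                    "summary": f"{clinical[col].median():.1f} ({clinical[col].min():.1f}-{clinical[col].max():.1f})",
                }
            )
            continue
        if col not in known:
            raise ValidationError(f"unknown covariate {col!r} in clinical table")
        if clinical[col].isna().all():
            continue
        k = int(clinical[col].sum())
        rows.append({"characteristic": col, "summary": f"{k} ({100.0 * k / n:.1f})"})
    return pd.DataFrame(rows, columns=["characteristic", "summary"])


def write_report(report: AnalysisReport, outdir: str | os.PathLike) -> None:
    """Write all report artifacts as CSV plus the JSON run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.sample_metrics.to_csv(outdir / "sample_metrics.csv", index=False)
    report.course_metrics.to_csv(outdir / "course_metrics.csv", index=False)
    report.network_summary.to_csv(outdir / "network_summary.csv", index=False)
    report.km_summaries.to_csv(outdir / "km_summaries.csv", index=False)
    report.cox_table.to_csv(outdir / "cox_table.csv", index=False)
    report.clonality_association.to_csv(outdir / "clonality_association.csv", index=False)
    report.qc_exclusions.to_csv(outdir / "qc_exclusions.csv", index=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(report.run_log, fh, indent=1)
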