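"""Survival association layer: Kaplan-Meier, log-rank, Cox PH, selection.

Kaplan-Meier estimation and the log-rank test go through ``lifelines``;
Cox proportional-hazards models are fit with ``statsmodels`` PHReg, which
supports both Efron (default) and Breslow handling of tied event times
and reports per-term hazard ratios with Wald 95% confidence intervals and
p-values. The multivariable model is built by pure backward elimination:
refit after removing the single worst term until every remaining term has
Wald p below the retention threshold (default 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg

from .errors import ConvergenceError, ValidationError

__all__ = [
    "NOT_REACHED",
    "KMCurve",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "backward_select",
    "covariate_association_with_rcl",
]

#: Literal token used in report tables for an unreached median.
NOT_REACHED = "NR"

# a Wald standard error this large on a log-HR signals monotone likelihood
_SE_DIVERGED = 50.0


@dataclass
class KMCurve:
    """Product-limit survival curve. ``median`` is None when never reached."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None
    n: int
    n_events: int


@dataclass
class CoxResult:
    """Per-term hazard ratios with Wald 95% CIs and p-values."""

    terms: list[str]
    hr: dict[str, float] = field(default_factory=dict)
    ci_lower: dict[str, float] = field(default_factory=dict)
    ci_upper: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    log_likelihood: float = np.nan
    n_subjects: int = 0
    n_events: int = 0
    removal_trace: list[tuple[str, float]] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "hr": [self.hr[t] for t in self.terms],
                "ci_lower": [self.ci_lower[t] for t in self.terms],
                "ci_upper": [self.ci_upper[t] for t in self.terms],
                "p": [self.p[t] for t in self.terms],
            }
        )


def _validate_surv(df: pd.DataFrame) -> None:
    if "os_months" not in df.columns or "event" not in df.columns:
        raise ValidationError("survival frame needs 'os_months' and 'event' columns")
    if len(df) == 0:
        raise ValidationError("empty survival input")


def km_estimate(df: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimate of overall survival.

    The median is the smallest time at which the curve falls to <= 0.5, or
    None ("not reached") when it never does.
    """
    _validate_surv(df)
    kmf = KaplanMeierFitter()
    kmf.fit(df["os_months"], event_observed=df["event"])
    med = kmf.median_survival_time_
    table = kmf.event_table
    return KMCurve(
        times=kmf.survival_function_.index.to_numpy(),
        survival=kmf.survival_function_["KM_estimate"].to_numpy(),
        at_risk=table["at_risk"].to_numpy(),
        median=None if np.isinf(med) else float(med),
        n=int(len(df)),
        n_events=int(df["event"].sum()),
    )


def logrank_test(labels, df: pd.DataFrame) -> tuple[float, float]:
    """Two-or-more-sample log-rank test; returns (chi-square, p)."""
    _validate_surv(df)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValidationError(f"log-rank needs >= 2 non-empty groups, got {len(groups)}")
    if (counts == 0).any():  # pragma: no cover - unique() never returns empties
        raise ValidationError("log-rank groups must be non-empty")
    res = multivariate_logrank_test(df["os_months"], labels, df["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(df: pd.DataFrame, terms: list[str], ties: str = "efron") -> CoxResult:
    """Fit a Cox proportional-hazards model by partial likelihood.

    ``df`` must carry ``os_months``, ``event`` and every column in
    ``terms``. Hazard ratios are exp(coef) with Wald 95% CIs.

    Raises
    ------
    ValidationError
        If there are no events or a covariate is constant.
    ConvergenceError
        On monotone likelihood / complete separation, naming the term.
    """
    _validate_surv(df)
    if ties not in {"efron", "breslow"}:
        raise ValidationError(f"unknown ties method {ties!r}")
    if df["event"].sum() == 0:
        raise ValidationError("Cox model requires at least one observed event")
    if not terms:
        return CoxResult(terms=[], n_subjects=len(df), n_events=int(df["event"].sum()))
    for t in terms:
        if df[t].nunique() <= 1:
            raise ValidationError(f"covariate {t!r} is constant across subjects")

    X = df[terms].to_numpy(dtype=float)
    model = PHReg(df["os_months"].to_numpy(dtype=float), X, status=df["event"].to_numpy(dtype=int), ties=ties)
    import warnings

    try:
        with warnings.catch_warnings():
            # divergence is diagnosed below from the Wald standard errors
            warnings.simplefilter("ignore")
            fit = model.fit(disp=False)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"Cox fit failed for terms {terms}: {exc}") from exc

    se = np.asarray(fit.bse, dtype=float)
    coef = np.asarray(fit.params, dtype=float)
    bad = ~np.isfinite(se) | (se > _SE_DIVERGED) | ~np.isfinite(coef)
    if bad.any():
        culprit = terms[int(np.argmax(bad))]
        raise ConvergenceError(
            f"Cox fit did not converge (monotone likelihood or separation) for term {culprit!r}"
        )

    z = 1.959963984540054  # Phi^{-1}(0.975)
    result = CoxResult(
        terms=list(terms),
        log_likelihood=float(model.loglike(fit.params)),
        n_subjects=len(df),
        n_events=int(df["event"].sum()),
    )
    pvals = np.asarray(fit.pvalues, dtype=float)
    for i, t in enumerate(terms):
        result.hr[t] = float(np.exp(coef[i]))
        result.ci_lower[t] = float(np.exp(coef[i] - z * se[i]))
        result.ci_upper[t] = float(np.exp(coef[i] + z * se[i]))
        result.p[t] = float(pvals[i])
    return result


def backward_select(
    df: pd.DataFrame, full_terms: list[str], p_keep: float = 0.2, ties: str = "efron"
) -> CoxResult:
    """Pure backward elimination on the full Cox model.

    Iteratively refits, removing the single term with the largest Wald
    p >= ``p_keep``, until every remaining term has p < ``p_keep``. An
    all-noise model may end empty; the empty model is returned without
    error, with the removal trace attached.
    """
    terms = list(full_terms)
    trace: list[tuple[str, float]] = []
    while True:
        result = cox_fit(df, terms, ties=ties)
        if not terms:
            break
        worst = max(terms, key=lambda t: result.p[t])
        if result.p[worst] < p_keep:
            break
        trace.append((worst, result.p[worst]))
        terms.remove(worst)
    result.removal_trace = trace
    return result


def covariate_association_with_rcl(
    df: pd.DataFrame, covariates: list[str], outcome: str = "increased_clonality"
) -> pd.DataFrame:
    """Multivariable logistic regression of the increased-clonality indicator.

    Fits a binomial-family model of the binary outcome on the clinical
    covariate set and reports per-covariate log-odds, odds ratio and Wald
    p-value. Covariates constant across patients are dropped (reported
    with ``excluded=True``).

    Raises
    ------
    ValidationError
        If fewer than 10 patients carry the outcome label.
    ConvergenceError
        On complete separation.
    """
    import statsmodels.api as sm

    data = df.dropna(subset=[outcome]).copy()
    if len(data) < 10:
        raise ValidationError(f"need >= 10 patients with defined {outcome!r}, got {len(data)}")

    kept, dropped = [], []
    for c in covariates:
        (kept if data[c].nunique() > 1 else dropped).append(c)

    y = data[outcome].astype(float)
    X = sm.add_constant(data[kept].astype(float))
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - statsmodels raises various types
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if (~np.isfinite(fit.bse)).any() or (np.asarray(fit.bse) > _SE_DIVERGED).any():
        raise ConvergenceError("logistic fit shows complete separation (diverging standard error)")

    rows = []
    for c in kept:
        rows.append(
            {
                "term": c,
                "log_odds": float(fit.params[c]),
                "odds_ratio": float(np.exp(fit.params[c])),
                "p": float(fit.pvalues[c]),
                "excluded": False,
            }
        )
    for c in dropped:
        rows.append({"term": c, "log_odds": np.nan, "odds_ratio": np.nan, "p": np.nan, "excluded": True})
    return pd.DataFrame(rows, columns=["term", "log_odds", "odds_ratio", "p", "excluded"])
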