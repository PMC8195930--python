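"""Kaplan-Meier, log-rank, Cox PH (both tie methods), and model selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tcrdyn.errors import ConvergenceError, ValidationError
from tcrdyn.simulate import simulate_survival
from tcrdyn.survival import (
    backward_select,
    covariate_association_with_rcl,
    cox_fit,
    km_estimate,
    logrank_test,
)


def surv_frame(times, events, **covs):
    return pd.DataFrame({"os_months": times, "event": events, **covs})


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        df = surv_frame([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        curve = km_estimate(df)
        s = dict(zip(curve.times, curve.survival))
        assert s[3.0] == pytest.approx(0.4)
        assert curve.median == pytest.approx(3.0)

    def test_all_censored_median_not_reached(self):
        curve = km_estimate(surv_frame([2, 4, 6], [0, 0, 0]))
        assert np.allclose(curve.survival, 1.0)
        assert curve.median is None

    def test_single_event_median_at_first_half_survival(self):
        curve = km_estimate(surv_frame([2, 5], [1, 0]))
        s = dict(zip(curve.times, curve.survival))
        assert s[2.0] == pytest.approx(0.5)
        assert curve.median == pytest.approx(2.0)

    def test_fully_observed_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=50).round(3)
        df = surv_frame(times, np.ones(50, dtype=int))
        curve = km_estimate(df)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate(surv_frame([], []))


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        df = surv_frame([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        stat, p = logrank_test(["a", "a", "a", "b", "b", "b"], df)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        df = simulate_survival(80, 0.7, rng)
        labels = np.where(df["x"] == 1, "g1", "g0")
        stat1, p1 = logrank_test(labels, df)
        swapped = np.where(labels == "g1", "g0", "g1")
        stat2, p2 = logrank_test(swapped, df)
        assert stat1 == pytest.approx(stat2) and p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        df = surv_frame([1, 2], [1, 1])
        with pytest.raises(ValidationError):
            logrank_test(["a", "a"], df)

    def test_power_under_strong_hazard_ratio(self):
        """HR 3, n=500/arm, no censoring: p < 0.05 in >= 95% of 200 replicates."""
        hits = 0
        for seed in range(200):
            r = np.random.default_rng(1000 + seed)
            t0 = r.exponential(1.0, size=500)
            t1 = r.exponential(1.0 / 3.0, size=500)
            df = surv_frame(np.concatenate([t0, t1]), np.ones(1000, dtype=int))
            _, p = logrank_test(["a"] * 500 + ["b"] * 500, df)
            hits += p < 0.05
        assert hits >= 0.95 * 200


class TestCoxFit:
    def test_null_covariate_recovery(self):
        """Mean log-HR across 200 null simulations lies within 3 SE of 0."""
        coefs, ses = [], []
        for seed in range(200):
            r = np.random.default_rng(2000 + seed)
            df = simulate_survival(300, 0.0, r)
            res = cox_fit(df, ["x"])
            coefs.append(np.log(res.hr["x"]))
            ses.append((np.log(res.ci_upper["x"]) - np.log(res.ci_lower["x"])) / (2 * 1.96))
        mean_se = np.mean(ses) / np.sqrt(len(coefs))
        assert abs(np.mean(coefs)) < 3 * mean_se

    def test_true_hr_two_recovery(self):
        """True HR 2.0, n=500, ~30% censoring: mean estimate in [1.8, 2.2]."""
        hrs = []
        for seed in range(200):
            r = np.random.default_rng(3000 + seed)
            df = simulate_survival(500, np.log(2.0), r)
            hrs.append(cox_fit(df, ["x"]).hr["x"])
        assert 1.8 <= np.mean(hrs) <= 2.2

    def test_all_censored_rejected(self):
        df = surv_frame([1, 2, 3], [0, 0, 0], x=[0, 1, 0])
        with pytest.raises(ValidationError):
            cox_fit(df, ["x"])

    def test_constant_covariate_rejected(self):
        df = surv_frame([1, 2, 3], [1, 1, 0], x=[1, 1, 1])
        with pytest.raises(ValidationError):
            cox_fit(df, ["x"])

    def test_complete_separation_diagnosed(self):
        # covariate perfectly orders survival: monotone likelihood
        times = np.concatenate([np.arange(1, 21), np.arange(100, 120)])
        df = surv_frame(times, np.ones(40, dtype=int), x=[1] * 20 + [0] * 20)
        with pytest.raises(ConvergenceError, match="x"):
            cox_fit(df, ["x"])

    def test_ties_methods_agree_on_distinct_event_times(self, rng):
        df = simulate_survival(120, 0.5, rng)
        df["os_months"] = df["os_months"] + rng.uniform(0, 1e-6, size=len(df))  # break ties
        efron = cox_fit(df, ["x"], ties="efron")
        breslow = cox_fit(df, ["x"], ties="breslow")
        assert efron.hr["x"] == pytest.approx(breslow.hr["x"], rel=1e-6)
        assert efron.p["x"] == pytest.approx(breslow.p["x"], rel=1e-6)

    def test_matches_lifelines_cross_check(self, rng):
        """Independent fit of the same partial likelihood via lifelines (Efron)."""
        from lifelines import CoxPHFitter

        df = simulate_survival(150, 0.8, rng)
        df["z"] = rng.normal(size=len(df))
        ours = cox_fit(df, ["x", "z"], ties="efron")
        cph = CoxPHFitter().fit(df[["os_months", "event", "x", "z"]], "os_months", "event")
        for term in ("x", "z"):
            assert ours.hr[term] == pytest.approx(cph.hazard_ratios_[term], rel=1e-4)
            assert ours.p[term] == pytest.approx(cph.summary.loc[term, "p"], rel=1e-3, abs=1e-6)


class TestBackwardSelect:
    def test_fixed_point_when_all_terms_significant(self, rng):
        df = simulate_survival(400, np.log(3.0), rng)
        full = cox_fit(df, ["x"])
        final = backward_select(df, ["x"], p_keep=0.2)
        assert final.terms == ["x"]
        assert final.hr["x"] == pytest.approx(full.hr["x"])
        assert final.removal_trace == []

    def test_never_removes_significant_terms_and_terminates(self, rng):
        df = simulate_survival(300, np.log(2.5), rng)
        for k in range(4):
            df[f"noise{k}"] = rng.binomial(1, 0.5, size=len(df))
        terms = ["x"] + [f"noise{k}" for k in range(4)]
        final = backward_select(df, terms, p_keep=0.2)
        assert len(final.removal_trace) <= len(terms)
        assert all(p >= 0.2 for _, p in final.removal_trace)
        assert all(final.p[t] < 0.2 for t in final.terms)

    def test_recovers_true_covariate_among_noise(self):
        """One true HR-2 covariate + 5 noise: retained in >= 90% of 100 replicates."""
        kept = 0
        for seed in range(100):
            r = np.random.default_rng(4000 + seed)
            df = simulate_survival(400, np.log(2.0), r)
            for k in range(5):
                df[f"noise{k}"] = r.binomial(1, 0.5, size=len(df))
            final = backward_select(df, ["x"] + [f"noise{k}" for k in range(5)], p_keep=0.2)
            kept += "x" in final.terms
        assert kept >= 90

    def test_all_noise_may_end_empty_without_error(self):
        r = np.random.default_rng(77)
        df = simulate_survival(60, 0.0, r)
        df["n1"] = r.binomial(1, 0.5, size=60)
        df["n2"] = r.binomial(1, 0.5, size=60)
        final = backward_select(df, ["n1", "n2"], p_keep=1e-6)
        assert final.terms == []


class TestClonalityAssociation:
    @staticmethod
    def _cohort(r, n, effect=0.0):
        male = r.binomial(1, 0.5, size=n)
        liver = r.binomial(1, 0.3, size=n)
        logit = -0.85 + effect * male
        p = 1 / (1 + np.exp(-logit))
        return pd.DataFrame(
            {
                "increased_clonality": r.binomial(1, p),
                "male_sex": male,
                "liver_mets": liver,
            }
        )

    def test_constant_covariate_excluded_with_reason(self, rng):
        df = self._cohort(rng, 60)
        df["squamous"] = 1
        out = covariate_association_with_rcl(df, ["male_sex", "liver_mets", "squamous"])
        assert bool(out.set_index("term").loc["squamous", "excluded"])
        assert not out.set_index("term").loc["male_sex", "excluded"]

    def test_power_for_real_effect(self):
        """male_sex shifting P(increase) 0.3->0.7 detected in >= 80% of 100 reps, n=200."""
        effect = np.log(0.7 / 0.3) - np.log(0.3 / 0.7)  # log-odds shift 0.3 -> 0.7
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(5000 + seed)
            df = self._cohort(r, 200, effect=effect)
            out = covariate_association_with_rcl(df, ["male_sex", "liver_mets"]).set_index("term")
            hits += out.loc["male_sex", "p"] < 0.05
        assert hits >= 80

    def test_null_p_values_approximately_uniform(self):
        """No-association simulation: KS test vs uniform over 500 replicates."""
        from scipy import stats

        ps = []
        for seed in range(500):
            r = np.random.default_rng(6000 + seed)
            df = self._cohort(r, 200)
            out = covariate_association_with_rcl(df, ["male_sex", "liver_mets"]).set_index("term")
            ps.append(out.loc["male_sex", "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_requires_ten_labelled_patients(self, rng):
        df = self._cohort(rng, 5)
        with pytest.raises(ValidationError):
            covariate_association_with_rcl(df, ["male_sex"])
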