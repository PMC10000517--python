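"""Kaplan-Meier, log-rank, and Cox model against hand and library oracles."""

import numpy as np
import pandas as pd
import pytest

from exonsurv.model import CohortLabels, ValidationError
from exonsurv.survival import (
    build_covariates,
    cox_fit,
    cox_score_test,
    km_fit,
    logrank_test,
    median_survival,
    run_outcome_analysis,
)
from exonsurv.simulate import (
    SyntheticSpec,
    planted_truth,
    simulate_clinical,
    simulate_survival,
)


class TestKaplanMeier:
    def test_three_events_product_limit(self):
        km = km_fit([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert list(km.at_risk) == [3, 2, 1]

    def test_all_censored_is_flat_one(self):
        km = km_fit([5, 8, 13], [0, 0, 0])
        assert km.survival.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_mixed_censoring_hand_table(self):
        # subjects: 1(ev), 2(cens), 3(ev), 4(ev), 4(ev), 5(cens)
        # t=1: 1/6 -> S=5/6; t=3: risk 4, d=1 -> 5/6*3/4=0.625;
        # t=4: risk 3, d=2 -> 0.625/3
        km = km_fit([1, 2, 3, 4, 4, 5], [1, 0, 1, 1, 1, 0])
        assert np.allclose(km.survival, [5 / 6, 0.625, 0.625 / 3])
        assert list(km.events) == [1, 1, 2]
        assert list(km.at_risk) == [6, 4, 3]
        # Greenwood variance at the first event time: S^2 * d/(n(n-d))
        assert km.variance[0] == pytest.approx((5 / 6) ** 2 * 1 / 30)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(50, size=200)
        km = km_fit(t, np.ones(200))
        for ti in km.times:
            assert km.survival_at(ti) == pytest.approx(np.mean(t > ti), abs=1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(21)
        t = np.round(rng.exponential(30, 150)) + 1
        e = rng.binomial(1, 0.6, 150)
        km = km_fit(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        S = kmf.survival_function_.loc[km.times, "KM_estimate"].to_numpy()
        assert np.allclose(km.survival, S, atol=1e-12)

    def test_survival_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(4)
        km = km_fit(rng.exponential(10, 100), rng.binomial(1, 0.5, 100))
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert np.all((km.survival >= 0) & (km.survival <= 1))
        assert np.all(np.diff(km.at_risk) <= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_fit([], [])


class TestMedianSurvival:
    def test_single_drop_below_half(self):
        med = median_survival(km_fit([100] * 10, [1] * 6 + [0] * 4))
        assert med.median == 100.0

    def test_plateau_above_half_undefined(self):
        # 2 of 10 events: S plateaus at 0.8
        med = median_survival(km_fit([50, 60] + [100] * 8, [1, 1] + [0] * 8))
        assert med.median is None
        assert med.ci_upper is None

    def test_exponential_cohort_recovers_true_median(self):
        rng = np.random.default_rng(123)
        true_median = 1008.0
        t = rng.exponential(true_median / np.log(2), size=5000)
        med = median_survival(km_fit(t, np.ones(5000)))
        assert med.median == pytest.approx(true_median, rel=0.05)
        assert med.ci_lower < med.median < med.ci_upper

    def test_ci_band_crossings_ordered(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(100, 300)
        e = rng.binomial(1, 0.8, 300)
        med = median_survival(km_fit(t, e))
        assert med.ci_lower <= med.median <= med.ci_upper


def _hand_logrank(times, events, group):
    """Independent log-rank oracle: direct accumulation at each event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group)
    o_minus_e = 0.0
    v = 0.0
    for et in sorted(set(times[events == 1])):
        at = times >= et
        n, n1 = at.sum(), (at & (group == group[0])).sum()
        d = ((times == et) & (events == 1)).sum()
        d1 = ((times == et) & (events == 1) & (group == group[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v if v > 0 else 0.0


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = [3, 5, 8, 12]
        km_args = (t + t, [1, 1, 0, 1] * 2, [0] * 4 + [1] * 4)
        res = logrank_test(*km_args)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_eight_subject_hand_fixture(self):
        t = [6, 7, 10, 15, 19, 25, 30, 34]
        e = [1, 0, 1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(_hand_logrank(t, e, g), abs=1e-12)
        assert np.isclose(res.observed.sum(), res.expected.sum())

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(31)
        t = rng.exponential(20, 60)
        e = rng.binomial(1, 0.7, 60)
        g = rng.binomial(1, 0.5, 60)
        if g.sum() in (0, 60):
            g[0] = 1 - g[0]
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2, 3], [1, 1, 0], [0, 0, 0])


def _naive_cox_loglik(beta, x, times, events):
    """Independent log partial likelihood (Efron) for a single covariate."""
    ll = 0.0
    for et in sorted(set(times[events == 1])):
        dead = (times == et) & (events == 1)
        at_risk = times >= et
        d = dead.sum()
        s0 = np.sum(np.exp(beta * x[at_risk]))
        s0d = np.sum(np.exp(beta * x[dead]))
        ll += beta * x[dead].sum()
        for l in range(d):
            ll -= np.log(s0 - (l / d) * s0d)
    return ll


class TestCox:
    def test_constant_covariate_flagged_non_identifiable(self):
        fit = cox_fit(np.ones((20, 1)), np.arange(1, 21),
                      np.ones(20), names=["flat"])
        assert fit.summary.loc["flat", "coef"] == 0.0
        assert np.isinf(fit.summary.loc["flat", "se"])
        assert any("non-identifiable" in f for f in fit.flags)

    def test_grid_search_oracle_ten_subjects(self):
        rng = np.random.default_rng(17)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 1], dtype=float)
        t = rng.exponential(10 * np.exp(-0.8 * x))
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1])
        fit = cox_fit(x.reshape(-1, 1), t, e)
        # coarse-to-fine grid search of the naive log partial likelihood
        grid = np.arange(-3, 3, 0.01)
        lls = [_naive_cox_loglik(b, x, t, e) for b in grid]
        best = grid[int(np.argmax(lls))]
        fine = np.arange(best - 0.02, best + 0.02, 1e-4)
        lls = [_naive_cox_loglik(b, x, t, e) for b in fine]
        best = fine[int(np.argmax(lls))]
        assert fit.coef[0] == pytest.approx(best, abs=1e-4)

    def test_matches_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(6)
        n = 120
        X = np.column_stack([rng.binomial(1, 0.3, n), rng.normal(size=n)])
        t = np.round(rng.exponential(40 * np.exp(-0.6 * X[:, 0])), 0) + 1
        e = rng.binomial(1, 0.75, n)
        fit = cox_fit(X, t, e)
        df = pd.DataFrame({"t": t, "e": e, "a": X[:, 0], "b": X[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.coef, cph.params_[["a", "b"]], atol=1e-6)
        assert np.allclose(
            fit.summary["se"], cph.standard_errors_[["a", "b"]], atol=1e-6
        )
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_hr_and_ci_consistency(self):
        rng = np.random.default_rng(14)
        x = rng.binomial(1, 0.5, 60).astype(float)
        t = rng.exponential(10 * np.exp(-0.5 * x))
        fit = cox_fit(x.reshape(-1, 1), t, np.ones(60))
        row = fit.summary.iloc[0]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]), rel=1e-12)
        assert row["hr_lower"] == pytest.approx(
            np.exp(row["coef"] - 1.959963984540054 * row["se"]), rel=1e-9
        )

    def test_two_group_exponential_recovers_hr(self):
        n = 4000
        x = np.repeat([0.0, 1.0], n // 2)
        lam = np.log(2) / 2029.0 * 2.3**x
        hrs = []
        for seed in (1, 2, 3):
            t = np.random.default_rng(seed).exponential(1 / lam)
            hrs.append(cox_fit(x.reshape(-1, 1), t, np.ones(n)).hazard_ratios[0])
        assert np.mean(hrs) == pytest.approx(2.3, rel=0.10)

    def test_time_transform_invariance(self):
        rng = np.random.default_rng(55)
        x = rng.binomial(1, 0.4, 100).astype(float)
        t = rng.exponential(10 * np.exp(-0.7 * x))
        e = rng.binomial(1, 0.8, 100)
        a = cox_fit(x.reshape(-1, 1), t, e)
        b = cox_fit(x.reshape(-1, 1), 2 * t, e)
        assert a.coef[0] == pytest.approx(b.coef[0], abs=1e-9)

    def test_score_test_equals_logrank_breslow(self):
        rng = np.random.default_rng(70)
        for _ in range(20):
            n = int(rng.integers(20, 60))
            g = rng.binomial(1, 0.5, n).astype(float)
            if g.sum() in (0, n):
                continue
            t = rng.exponential(10, n)     # continuous: no ties
            e = rng.binomial(1, 0.7, n)
            if e.sum() == 0:
                continue
            lr = logrank_test(t, e, g)
            sc = cox_score_test(g.reshape(-1, 1), t, e, ties="breslow")
            assert sc == pytest.approx(lr.chi_square, abs=1e-8)

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            cox_fit(np.ones((5, 1)), [1, 2, 3, 4, 5], np.zeros(5))


@pytest.fixture(scope="module")
def cohort():
    spec = SyntheticSpec()
    truth = planted_truth(spec, 5150)
    covs = simulate_clinical(spec, truth, 5150)
    clinical = simulate_survival(spec, truth, covs, 5150)
    labels = CohortLabels(labels=truth.rename("label"), threshold=0.8,
                          target_exon="E12")
    return clinical, labels


class TestOutcomeAnalysis:
    def test_report_structure(self, cohort):
        clinical, labels = cohort
        reports = run_outcome_analysis(clinical, labels)
        assert set(reports) == {"relapse", "lfs", "os"}
        os_rep = reports["os"]
        assert set(os_rep.km) == {"low", "other"}
        assert {"low", "age_risk", "male", "poor_marker", "wbc",
                "mrd_positive"} == set(os_rep.univariate.index)
        assert os_rep.multivariate.converged

    def test_low_hr_direction(self, cohort):
        clinical, labels = cohort
        rep = run_outcome_analysis(clinical, labels, endpoints=("os",))["os"]
        assert rep.multivariate.summary.loc["low", "hr"] > 1.0

    def test_high_risk_subset_counts(self, cohort):
        clinical, labels = cohort
        rep = run_outcome_analysis(
            clinical, labels, endpoints=("os",), subset="high-risk"
        )["os"]
        n_high = int((clinical.df["nci_risk"] == "high").sum())
        assert rep.n == n_high

    def test_constant_covariates_collapse_to_univariate(self, cohort):
        """With every covariate but low-status constant, the multivariate HR
        equals the univariate HR for low status."""
        clinical, labels = cohort
        frame = clinical.df.copy()
        frame["sex"] = "male"
        frame["age_years"] = 5.0
        frame["wbc"] = 30.0
        frame["mrd_day29"] = 0.0
        frame["markers"] = [frozenset()] * len(frame)
        from exonsurv.model import ClinicalTable

        flat = ClinicalTable(df=frame)
        rep = run_outcome_analysis(flat, labels, endpoints=("os",))["os"]
        uni = rep.univariate.loc["low", "hr"]
        multi = rep.multivariate.summary.loc["low", "hr"]
        assert multi == pytest.approx(uni, rel=1e-9)

    def test_missing_endpoint_rejected(self, cohort):
        clinical, labels = cohort
        with pytest.raises(ValidationError):
            run_outcome_analysis(clinical, labels, endpoints=("efs",))

    def test_random_labels_null_calibration(self):
        """Labels carrying no signal: log-rank p approximately uniform."""
        spec = SyntheticSpec()
        spec.survival.hazard_ratio_low = {"relapse": 1.0, "lfs": 1.0, "os": 1.0}
        rng = np.random.default_rng(88)
        pvals = []
        for seed in range(150):
            truth = planted_truth(spec, seed)
            covs = simulate_clinical(spec, truth, seed)
            clinical = simulate_survival(spec, truth, covs, seed)
            lr = logrank_test(
                clinical.df["os_time"], clinical.df["os_event"],
                truth.to_numpy(),
            )
            pvals.append(lr.p_value)
        rate = np.mean(np.asarray(pvals) < 0.05)
        # binomial 3-sigma band around 0.05 at 150 draws
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / 150) <= rate \
            <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 150)
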