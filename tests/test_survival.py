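"""Kaplan-Meier, log-rank, Cox PH (Efron) and landmark analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from melasig.errors import (
    DataIntegrityError,
    DegenerateInputError,
    EmptyResultError,
    ParameterError,
)
from melasig.survival import (
    DAYS_PER_YEAR,
    cox_fit,
    km_estimate,
    landmark_filter,
    logrank_test,
)


def logrank_oracle(ta, ea, tb, eb):
    """Direct observed-minus-expected summation with hypergeometric variance."""
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    O = E = V = 0.0
    for tt in np.unique(t[e == 1]):
        at = t >= tt
        n, n1 = at.sum(), (at & (g == 0)).sum()
        d = ((t == tt) & (e == 1)).sum()
        d1 = ((t == tt) & (e == 1) & (g == 0)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def efron_loglik(beta, times, events, x):
    """Explicit Efron partial log-likelihood for a single covariate."""
    ll = 0.0
    for tt in np.unique(times[events == 1]):
        D = (times == tt) & (events == 1)
        R = times >= tt
        d = D.sum()
        eR = np.exp(beta * x[R]).sum()
        eD = np.exp(beta * x[D]).sum()
        ll += beta * x[D].sum() - sum(np.log(eR - (l / d) * eD) for l in range(d))
    return ll


class TestKaplanMeier:
    def test_no_events_stays_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_single_death_closed_form(self):
        km = km_estimate([2.0, 3.0, 4.0, 5.0], [1, 0, 0, 0])
        assert km.set_index("time").loc[2.0, "survival"] == pytest.approx(0.75)

    def test_mixed_censoring_matches_hand_table(self):
        km = km_estimate([1, 2, 2, 3, 4, 4, 5, 6], [1, 0, 1, 1, 0, 1, 0, 0]).set_index("time")
        # product-limit by hand: deaths at 1,2,3,4 with at-risk 8,7,5,4
        expect = {1.0: 7 / 8, 2.0: 7 / 8 * 6 / 7, 3.0: 0.75 * 4 / 5, 4.0: 0.6 * 3 / 4}
        for t, s in expect.items():
            assert km.loc[t, "survival"] == pytest.approx(s, abs=1e-12)
        assert km.loc[0.0, "survival"] == 1.0
        assert km.loc[1.0, "at_risk"] == 8
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_all_events_no_ties_is_empirical_survival(self):
        times = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        km = km_estimate(times, np.ones(5, int)).set_index("time")
        for i, t in enumerate(sorted(times)):
            assert km.loc[t, "survival"] == pytest.approx(1 - (i + 1) / 5)

    def test_non_positive_time_rejected(self):
        with pytest.raises(DataIntegrityError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(3):
            ta = rng.exponential(1.0, 30)
            tb = rng.exponential(0.5, 25)
            ea = (rng.random(30) < 0.7).astype(int)
            eb = (rng.random(25) < 0.7).astype(int)
            stat, _ = logrank_test(ta, ea, tb, eb)
            assert stat == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-10)

    def test_invariant_to_common_time_rescaling(self):
        rng = np.random.default_rng(6)
        ta, tb = rng.exponential(1.0, 20), rng.exponential(0.6, 20)
        ea = eb = np.ones(20, int)
        s1, _ = logrank_test(ta, ea, tb, eb)
        s2, _ = logrank_test(ta * 365.25, ea, tb * 365.25, eb)
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_zero_events_undefined(self):
        with pytest.raises(ParameterError):
            logrank_test([1.0], [0], [2.0], [0])

    def test_power_at_true_hazard_ratio(self):
        """HR 2.2 at n=450 with ~60% events rejects in >= 80% of replicates."""
        rng = np.random.default_rng(11)
        reject = 0
        n_rep = 200
        for _ in range(n_rep):
            n1, n2 = 75, 375
            t1 = rng.exponential(1 / 2.2, n1)
            t2 = rng.exponential(1.0, n2)
            c1, c2 = rng.exponential(1 / 0.7, n1), rng.exponential(1 / 0.7, n2)
            _, p = logrank_test(
                np.minimum(t1, c1), (t1 <= c1).astype(int),
                np.minimum(t2, c2), (t2 <= c2).astype(int),
            )
            reject += p < 0.05
        assert reject / n_rep >= 0.80


class TestCox:
    def test_duplicated_outcomes_give_unit_hazard_ratio(self):
        half = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0, 5.0], "event": [1, 1, 0, 1, 1]}
        )
        df = pd.concat(
            [half.assign(cluster="UV-high"), half.assign(cluster="UV-low")],
            ignore_index=True,
        )
        fit = cox_fit(df, ["cluster"])
        assert fit.hr["cluster"] == pytest.approx(1.0, abs=1e-6)

    def test_binary_covariate_matches_partial_likelihood_oracle(self):
        times = np.array([3.0, 5.0, 5.0, 6.0, 8.0, 8.0, 9.0, 12.0, 14.0, 14.0, 16.0, 20.0])
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([1, 1, 0, 1, 0, 1, 0, 0, 1, 0, 1, 0], float)
        fit = cox_fit(pd.DataFrame({"time": times, "event": events, "age": x}), ["age"])
        oracle = minimize_scalar(
            lambda b: -efron_loglik(b, times, events, x),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10},
        ).x
        assert fit.coefficients["age"] == pytest.approx(oracle, abs=1e-4)

    def test_ci_is_exact_transform_of_coef_and_se(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "time": rng.exponential(1.0, 60),
                "event": (rng.random(60) < 0.7).astype(int),
                "age": rng.normal(60, 10, 60),
            }
        )
        fit = cox_fit(df, ["age"])
        lo, hi = fit.ci95["age"]
        c, s = fit.coefficients["age"], fit.se["age"]
        assert lo == pytest.approx(np.exp(c - 1.96 * s), rel=1e-12)
        assert hi == pytest.approx(np.exp(c + 1.96 * s), rel=1e-12)
        assert lo < fit.hr["age"] < hi
        assert fit.hr["age"] == pytest.approx(np.exp(c), rel=1e-12)

    def test_multivariate_covariate_coding(self, fitted_cohorts):
        from melasig.simulate import simulate_survival

        c = fitted_cohorts[0]
        clin = simulate_survival(c["truth"], c["spec"])
        fit = cox_fit(clin, ["cluster", "age", "sex", "stage", "mutation_class"])
        assert set(fit.coefficients) == {"cluster", "age", "sex", "stage", "mutation_class"}
        assert fit.n == len(clin)
        assert fit.n_events == int(clin["event"].sum())

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "event": [1, 1, 1], "cluster": ["UV-low"] * 3}
        )
        with pytest.raises(DegenerateInputError):
            cox_fit(df, ["cluster"])


class TestLandmark:
    def test_early_death_excluded_and_clock_reset(self):
        df = pd.DataFrame(
            {
                "time": [0.5 * DAYS_PER_YEAR, 3 * DAYS_PER_YEAR],
                "event": [1, 0],
            }
        )
        kept = landmark_filter(df, DAYS_PER_YEAR)
        assert len(kept) == 1
        assert kept["time"].iloc[0] == pytest.approx(2 * DAYS_PER_YEAR)

    def test_empty_landmark_rejected(self):
        df = pd.DataFrame({"time": [100.0], "event": [1]})
        with pytest.raises(EmptyResultError):
            landmark_filter(df, 200.0)

    def test_landmark_hr_consistent_under_proportional_hazards(self):
        """Exponential (memoryless) survival keeps the HR after the landmark."""
        from melasig.simulate import CohortSpec, simulate_survival

        hrs = []
        for s in range(20):
            spec = CohortSpec(n_samples=500, seed=s)
            rng = np.random.default_rng(300 + s)
            clusters = np.where(rng.random(500) < 0.5, "UV-high", "UV-low")
            truth = pd.DataFrame({"cluster": clusters},
                                 index=[f"S{i}" for i in range(500)])
            clin = simulate_survival(truth, spec, seed=600 + s)
            hrs.append(cox_fit(landmark_filter(clin), ["cluster"]).hr["cluster"])
        assert 1.8 <= np.mean(hrs) <= 2.7
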