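"""Censored time-to-event machinery: KM, log-rank, Cox PH."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from faindex.survival import (
    ConvergenceError,
    actuarial_life_table,
    class_factor_lr_test,
    kaplan_meier,
    log_rank_test,
    ph_regression,
)


def brute_force_logrank(time, event, group):
    """Independent O/E/V sums, written as explicit loops over event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    labels = sorted(set(group))
    k = len(labels)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in sorted(set(time[event == 1])):
        n_t = (time >= t).sum()
        d_t = ((time == t) & (event == 1)).sum()
        for j, lj in enumerate(labels):
            n_jt = ((group == lj) & (time >= t)).sum()
            d_jt = ((group == lj) & (time == t) & (event == 1)).sum()
            O[j] += d_jt
            E[j] += d_t * n_jt / n_t
        if n_t > 1:
            c = d_t * (n_t - d_t) / (n_t - 1)
            for j, lj in enumerate(labels):
                n_jt = ((group == lj) & (time >= t)).sum()
                for l, ll in enumerate(labels):
                    n_lt = ((group == ll) & (time >= t)).sum()
                    V[j, l] += c * ((j == l) * n_jt * n_t - n_jt * n_lt) / n_t**2
    diff = (O - E)[:-1]
    stat = float(diff @ np.linalg.solve(V[:-1, :-1], diff))
    return stat, O, E


class TestKaplanMeier:
    def test_no_events_gives_unit_survival_with_flag(self):
        with pytest.warns(UserWarning, match="all observations censored"):
            km = kaplan_meier([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert km.all_censored
        assert km.at([0.5, 10.0]).tolist() == [1.0, 1.0]

    def test_product_limit_by_hand(self):
        # events at t=1 (1 of 5 at risk) then t=2 (1 of 4): (4/5)*(3/4)
        km = kaplan_meier([1, 2, 3, 4, 5], [1, 1, 0, 0, 0])
        assert np.allclose(km.survival, [1.0, 0.8, 0.6])
        assert km.times.tolist() == [0.0, 1.0, 2.0]
        assert km.n_at_risk.tolist() == [5, 5, 4]

    def test_step_function_properties(self, rng):
        t = rng.exponential(10, 200)
        e = rng.random(200) < 0.7
        km = kaplan_meier(t, e.astype(int))
        assert km.survival[0] == 1.0
        assert np.all(np.diff(km.survival) <= 0)

    def test_uncensored_exponential_matches_closed_form(self, rng):
        lam = 0.05
        t = rng.exponential(1 / lam, 20_000)
        km = kaplan_meier(t, np.ones_like(t, dtype=int))
        sup = np.max(np.abs(km.survival - np.exp(-lam * km.times)))
        assert sup < 0.02

    def test_uncensored_km_is_one_minus_ecdf(self, rng):
        t = np.round(rng.exponential(5, 500), 1) + 0.1  # force ties
        km = kaplan_meier(t, np.ones_like(t, dtype=int))
        grid = np.quantile(t, [0.1, 0.5, 0.9])
        ecdf = np.array([(t <= g).mean() for g in grid])
        assert np.allclose(km.at(grid), 1 - ecdf, atol=1e-12)

    def test_positive_times_required(self):
        with pytest.raises(ValueError, match="positive"):
            kaplan_meier([0.0, 1.0], [1, 1])


class TestActuarialLifeTable:
    def test_matches_km_without_censoring_at_interval_ends(self, rng):
        t = rng.exponential(20, 2000)
        e = np.ones_like(t, dtype=int)
        lt = actuarial_life_table(t, e, interval_width=6.0)
        km = kaplan_meier(t, e)
        # with no censoring the actuarial estimate equals the ecdf complement
        for _, row in lt.iloc[:5].iterrows():
            assert row["survival"] == pytest.approx(
                float(km.at(row["interval_end"])[0]), abs=1e-9
            )


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        group = list("aaaabbbb")
        res = log_rank_test(time, event, group)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_small_fixture_matches_brute_force(self):
        # six subjects, ties and censoring included
        time = [3.0, 5.0, 5.0, 8.0, 10.0, 12.0]
        event = [1, 1, 0, 1, 0, 1]
        group = ["a", "b", "a", "b", "a", "b"]
        res = log_rank_test(time, event, group)
        stat, O, E = brute_force_logrank(time, event, group)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert np.allclose(res.observed, O)
        assert np.allclose(res.expected, E)
        assert res.expected.sum() == pytest.approx(res.observed.sum())

    def test_three_groups_match_brute_force_and_lifelines(self, rng):
        n = 120
        time = rng.exponential(10, n).round(1) + 0.1
        event = (rng.random(n) < 0.8).astype(int)
        group = rng.choice(["a", "b", "c"], n)
        res = log_rank_test(time, event, group)
        stat, _, _ = brute_force_logrank(time, event, group)
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        ll = multivariate_logrank_test(time, group, event)
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-6)
        assert res.df == 2

    def test_invariant_to_monotone_time_transform(self, rng):
        n = 80
        time = rng.exponential(10, n)
        event = (rng.random(n) < 0.7).astype(int)
        group = rng.choice(["a", "b"], n)
        res1 = log_rank_test(time, event, group)
        res2 = log_rank_test(np.sqrt(time), event, group)
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-12)

    def test_type_one_error_within_binomial_envelope(self):
        # 2000 null simulations, exponential both groups, n=50/group
        rng = np.random.default_rng(424242)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            t = rng.exponential(10, 100)
            e = (rng.random(100) < 0.8).astype(int)
            g = np.repeat(["a", "b"], 50)
            if log_rank_test(t, e, g).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sim
        half_width = 1.96 * math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < half_width

    def test_input_validation(self):
        with pytest.raises(ValueError, match="two groups"):
            log_rank_test([1, 2], [1, 1], ["a", "a"])
        with pytest.raises(ValueError, match="at least one event"):
            log_rank_test([1, 2], [0, 0], ["a", "b"])


def _simulate_two_group(rng, n_per_group, hr):
    t0 = rng.exponential(10.0, n_per_group)
    t1 = rng.exponential(10.0 / hr, n_per_group)
    time = np.concatenate([t0, t1])
    cens = rng.uniform(5, 40, 2 * n_per_group)
    x = np.repeat([0.0, 1.0], n_per_group)
    return pd.DataFrame(
        {
            "time": np.minimum(time, cens),
            "event": (time <= cens).astype(int),
            "x": x,
        }
    )


class TestPHRegression:
    def test_null_log_hr_near_zero(self, rng):
        df = _simulate_two_group(rng, 1500, hr=1.0)
        res = ph_regression(df, "time", "event", ["x"])
        assert abs(res.params["x"]) < 0.1

    def test_recovers_true_hr_two(self, rng):
        df = _simulate_two_group(rng, 2000, hr=2.0)
        res = ph_regression(df, "time", "event", ["x"])
        assert abs(res.params["x"] - math.log(2)) <= 0.1
        assert res.hazard_ratios()["x"] == pytest.approx(2.0, rel=0.15)

    def test_efron_matches_grid_search_of_partial_likelihood(self, rng):
        # one-parameter model: compare against direct maximization on a grid
        from statsmodels.duration.hazard_regression import PHReg

        df = _simulate_two_group(rng, 150, hr=1.7)
        res = ph_regression(df, "time", "event", ["x"])
        model = PHReg(df["time"], df[["x"]], status=df["event"], ties="efron")
        grid = np.linspace(-1.5, 1.5, 3001)
        ll = np.array([model.loglike(np.array([b])) for b in grid])
        assert abs(grid[np.argmax(ll)] - res.params["x"]) < 2e-3

    def test_breslow_ties_flag(self, rng):
        t = np.round(rng.exponential(10, 300), 0) + 1.0  # heavy ties
        df = pd.DataFrame(
            {"time": t, "event": (rng.random(300) < 0.8).astype(int),
             "x": rng.random(300)}
        )
        efron = ph_regression(df, "time", "event", ["x"], ties="efron")
        breslow = ph_regression(df, "time", "event", ["x"], ties="breslow")
        assert efron.ties_method == "efron"
        assert breslow.params["x"] != pytest.approx(efron.params["x"], abs=1e-9)

    def test_complete_separation_raises(self):
        # the covariate perfectly orders the event times: monotone likelihood
        df = pd.DataFrame(
            {"time": [1, 2, 3, 4, 10, 11, 12, 13],
             "event": [1] * 8,
             "x": [1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0]}
        )
        with pytest.raises((ConvergenceError, ValueError)):
            res = ph_regression(df, "time", "event", ["x"])
            # if the optimizer returned, estimates must have diverged
            raise ConvergenceError(str(res.params))

    def test_collinear_covariates_raise(self, rng):
        df = _simulate_two_group(rng, 100, hr=1.0)
        df["x2"] = 2 * df["x"]
        with pytest.raises(ValueError, match="collinear"):
            ph_regression(df, "time", "event", ["x", "x2"])

    def test_no_events_raise(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="not estimable"):
            ph_regression(df, "time", "event", ["x"])


class TestClassFactorLRTest:
    def test_lr_statistic_nonnegative_and_df(self, rng):
        df = _simulate_two_group(rng, 300, hr=1.8)
        df["fa_class"] = np.where(df["x"] == 1.0, "Frail", "Robust")
        df["age"] = rng.normal(72, 7, len(df))
        res = class_factor_lr_test(
            df, "time", "event", "fa_class", adjust_cols=["age"]
        )
        assert res.lr_statistic >= 0
        assert res.lr_df == 1
        assert res.lr_p < 0.01  # true HR 1.8 at n=600 is detectable

    def test_irrelevant_factor_lr_is_chi2_null(self):
        # LR stat for a random 2-level factor ~ chi-square(1): check the
        # upper tail over repeated simulations
        rng = np.random.default_rng(99)
        stats_ = []
        for _ in range(200):
            t = rng.exponential(10, 80)
            e = (rng.random(80) < 0.8).astype(int)
            df = pd.DataFrame(
                {"time": t, "event": e,
                 "fa_class": rng.choice(["Robust", "Frail"], 80)}
            )
            res = class_factor_lr_test(df, "time", "event", "fa_class")
            stats_.append(res.lr_statistic)
        stats_ = np.array(stats_)
        # empirical quantiles close to chi-square(1) quantiles
        emp_rej = (stats_ > stats.chi2.ppf(0.95, 1)).mean()
        assert abs(emp_rej - 0.05) < 0.05
        assert np.all(stats_ >= 0)


class TestCohortOrdering:
    def test_frail_survival_below_robust_on_simulated_cohort(self, default_cohort_10k):
        t = default_cohort_10k.table
        res = log_rank_test(t["observed_death_time"], t["death_event"], t["fa_class"])
        assert res.p_value < 1e-6
        km = {
            cls: kaplan_meier(
                t.loc[t["fa_class"] == cls, "observed_death_time"],
                t.loc[t["fa_class"] == cls, "death_event"],
            )
            for cls in ("Robust", "postRobust", "preFrail", "Frail")
        }
        s93 = {cls: float(k.at(92.9)[0]) for cls, k in km.items()}
        assert s93["Robust"] > s93["postRobust"] > s93["Frail"]
        assert s93["Robust"] > s93["preFrail"] > s93["Frail"]
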