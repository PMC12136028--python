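import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats
from scipy.optimize import minimize_scalar

from mdscore.errors import ConfigurationError, DegenerateDataError
from mdscore.survival import (
    cox_fit,
    kaplan_meier,
    log_rank,
    rmst,
    rmst_diff,
    schoenfeld_ph_test,
)


def random_survival_data(rng, n=None, p=1, effect=0.3):
    n = n or int(rng.integers(25, 80))
    X = rng.normal(size=(n, p))
    t = rng.exponential(5 * np.exp(-effect * X[:, 0]))
    c = rng.exponential(8, n)
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    return X, times, events


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_no_events_flat():
    curve = kaplan_meier([5, 10, 15], [0, 0, 0])
    assert curve.event_times.size == 0
    assert curve.at(20) == 1.0


def test_km_no_censoring_equals_one_minus_ecdf(rng):
    times = rng.exponential(5, 40)
    curve = kaplan_meier(times, np.ones(40, dtype=int))
    for t in np.linspace(0, times.max(), 17):
        assert curve.at(t) == pytest.approx((times > t).mean(), abs=1e-12)


def test_km_hand_example_with_tied_censor():
    # times {2,4,4,6}, events {1,1,0,1}: censor at 4 stays at risk at t=4
    curve = kaplan_meier([2, 4, 4, 6], [1, 1, 0, 1])
    assert np.allclose(curve.survival, [0.75, 0.5, 0.0])
    assert curve.n_at_risk.tolist() == [4, 3, 1]


def test_km_matches_lifelines(rng):
    times = rng.exponential(5, 60)
    events = rng.integers(0, 2, 60)
    if events.sum() == 0:
        events[0] = 1
    curve = kaplan_meier(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    ref = kmf.survival_function_at_times(curve.event_times).values
    assert np.allclose(curve.survival, ref, atol=1e-12)
    assert (np.diff(curve.survival) <= 1e-15).all()
    assert (curve.greenwood_var >= 0).all()
    # the cumulative Greenwood sum (var / S^2) is nondecreasing
    ok = curve.survival > 0
    gsum = curve.greenwood_var[ok] / curve.survival[ok] ** 2
    assert (np.diff(gsum) >= -1e-15).all()


def test_km_empty_errors():
    with pytest.raises(DegenerateDataError):
        kaplan_meier([], [])


# ---------------------------------------------------------------------------
# log-rank


def test_logrank_identical_groups_null():
    times = [3, 5, 7, 9, 30, 30]
    events = [1, 1, 1, 1, 0, 0]
    chi2, p = log_rank(times + times, events + events, [0] * 6 + [1] * 6)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_separated_groups_significant(rng):
    n = 500
    g = rng.integers(0, 2, n)
    t = rng.exponential(1 / (0.05 * 5.0**g))
    times = np.minimum(t, 30)
    events = (t <= 30).astype(int)
    _, p = log_rank(times, events, g)
    assert p < 1e-6


def test_logrank_hand_enumeration_small():
    # brute-force hypergeometric O-E sum on a 5-subject example
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    events = np.array([1, 1, 0, 1, 1])
    group = np.array([1, 0, 1, 1, 0])
    o_minus_e, var = 0.0, 0.0
    for t in times[events == 1]:
        risk = times >= t
        n, n1 = risk.sum(), (risk & (group == 1)).sum()
        dead = (times == t) & (events == 1)
        d, d1 = dead.sum(), (dead & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2, p = log_rank(times, events, group)
    assert chi2 == pytest.approx(o_minus_e**2 / var, abs=1e-12)


def test_logrank_matches_lifelines(rng):
    for _ in range(20):
        _, times, events = random_survival_data(rng)
        g = rng.integers(0, 2, len(times))
        if len(set(g)) < 2 or events.sum() == 0:
            continue
        chi2, p = log_rank(times, events, g)
        ref = logrank_test(times[g == 0], times[g == 1], events[g == 0], events[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-9)
        assert p == pytest.approx(ref.p_value, abs=1e-9)


def test_logrank_monotone_time_invariance(rng):
    _, times, events = random_survival_data(rng, n=50)
    g = rng.integers(0, 2, 50)
    g[:2] = [0, 1]
    chi2_a, _ = log_rank(times, events, g)
    chi2_b, _ = log_rank(np.exp(times / times.max()), events, g)
    assert chi2_a == pytest.approx(chi2_b, abs=1e-9)


def test_logrank_single_group_errors():
    with pytest.raises(DegenerateDataError):
        log_rank([1, 2], [1, 1], [0, 0])


# ---------------------------------------------------------------------------
# RMST


def test_rmst_no_deaths_is_tau():
    res = rmst_diff([30] * 6, [0] * 6, [0, 0, 0, 1, 1, 1], tau=30)
    assert res.rmst_per_group == [30.0, 30.0]
    assert res.diff == 0.0


def test_rmst_all_die_day10():
    area, _ = rmst([10] * 5, [1] * 5, tau=30)
    assert area == pytest.approx(10.0)


def test_rmst_step_area_matches_independent_integration(rng):
    for _ in range(20):
        _, times, events = random_survival_data(rng)
        if events.sum() == 0:
            continue
        tau = float(np.percentile(times, 80))
        area, _ = rmst(times, events, tau)
        # independent fine-grid rectangle integration of the step function
        curve = kaplan_meier(times, events)
        grid = np.union1d(curve.event_times[curve.event_times < tau], [0.0, tau])
        ref = sum(
            curve.at(a) * (b - a) for a, b in zip(grid[:-1], grid[1:])
        )
        assert area == pytest.approx(ref, abs=1e-12)


def test_rmst_matches_lifelines(rng):
    _, times, events = random_survival_data(rng, n=70)
    tau = float(np.percentile(times, 70))
    area, _ = rmst(times, events, tau)
    kmf = KaplanMeierFitter().fit(times, events)
    assert area == pytest.approx(restricted_mean_survival_time(kmf, t=tau), abs=1e-9)


def test_rmst_nondecreasing_in_tau(rng):
    _, times, events = random_survival_data(rng, n=50)
    areas = [rmst(times, events, tau)[0] for tau in (2, 5, 10, 20)]
    assert (np.diff(areas) >= -1e-12).all()


def test_rmst_diff_truncates_with_warning():
    with pytest.warns(UserWarning, match="truncating"):
        res = rmst_diff([5, 6, 20, 30], [1, 0, 1, 0], [0, 0, 1, 1], tau=40)
    assert res.rmst_per_group[0] <= 6.0


def test_rmst_diff_detects_strong_effect(rng):
    n = 400
    g = np.repeat([0, 1], n // 2)
    t = rng.exponential(np.where(g == 1, 5.0, 40.0))
    times = np.minimum(t, 30)
    events = (t <= 30).astype(int)
    res = rmst_diff(times, events, g, tau=30)
    assert res.diff < 0  # group 1 dies earlier
    assert res.diff_p < 1e-6


# ---------------------------------------------------------------------------
# Cox


def test_cox_null_binary_covariate(rng):
    n = 3000
    g = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(10, n)
    times = np.minimum(t, 30)
    events = (t <= 30).astype(int)
    fit = cox_fit(g, times, events)
    assert abs(fit.hr[0] - 1.0) < 0.15
    assert fit.p_lrt[0] > 0.001


def test_cox_recovers_planted_hr(rng):
    n = 2000
    g = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / (0.05 * 2.0**g))
    times = np.minimum(t, 30)
    events = (t <= 30).astype(int)
    fit = cox_fit(g, times, events)
    assert abs(fit.coef[0] - np.log(2.0)) < 3 * fit.se[0]
    assert fit.hr[0] == pytest.approx(np.exp(fit.coef[0]))
    lo, hi = fit.ci95[0]
    assert lo < fit.hr[0] < hi


def test_cox_toy_against_closed_form_partial_likelihood():
    # 4 subjects, 2 events: maximize the hand-written partial likelihood
    times = np.array([1.0, 2.0, 3.0, 4.0])
    events = np.array([1, 1, 0, 0])
    x = np.array([1.0, 0.0, 1.0, 0.0])

    def neg_pl(b):
        # event at t=1 (x=1), risk {all}; event at t=2 (x=0), risk {2,3,4}
        ll = b - np.log(np.exp(b) + 1 + np.exp(b) + 1)
        ll += 0.0 - np.log(1 + np.exp(b) + 1)
        return -ll

    ref = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded")
    fit = cox_fit(x, times, events)
    assert fit.coef[0] == pytest.approx(ref.x, abs=1e-5)
    assert fit.loglik == pytest.approx(-ref.fun, abs=1e-10)


def test_cox_matches_lifelines_oracle(rng):
    worst_coef = worst_p = 0.0
    done = 0
    while done < 25:
        p = int(rng.integers(1, 4))
        X, times, events = random_survival_data(rng, p=p)
        if events.sum() < 5:
            continue
        fit = cox_fit(X, times, events)
        df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
        df["T"], df["E"] = times, events
        cph = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-12})
        worst_coef = max(worst_coef, np.abs(fit.coef - cph.params_.values).max())
        ref_global = cph.log_likelihood_ratio_test().p_value
        worst_p = max(worst_p, abs(fit.global_lrt_p - ref_global))
        done += 1
    assert worst_coef < 1e-6
    assert worst_p < 1e-6


def test_cox_lrt_is_refit_based(rng):
    X, times, events = random_survival_data(rng, n=120, p=2)
    fit = cox_fit(X, times, events)
    red = cox_fit(X[:, [1]], times, events)
    expect = stats.chi2.sf(2 * (fit.loglik - red.loglik), 1)
    assert fit.p_lrt[0] == pytest.approx(expect, abs=1e-9)


def test_cox_efron_vs_breslow_on_ties(rng):
    times = np.repeat([2.0, 5.0, 9.0], 10)
    events = rng.integers(0, 2, 30)
    events[:3] = 1
    x = rng.normal(size=30)
    fe = cox_fit(x, times, events, ties="efron")
    fb = cox_fit(x, times, events, ties="breslow")
    assert fe.coef[0] != pytest.approx(fb.coef[0], abs=1e-9)  # ties matter
    df = pd.DataFrame({"x": x, "T": times, "E": events})
    ref = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-12})
    assert fe.coef[0] == pytest.approx(ref.params_.iloc[0], abs=1e-6)


def test_cox_errors_and_flags():
    with pytest.raises(DegenerateDataError, match="constant"):
        cox_fit(np.ones(10), np.arange(1.0, 11.0), np.ones(10, dtype=int))
    with pytest.raises(DegenerateDataError, match="event"):
        cox_fit(np.arange(10.0), np.arange(1.0, 11.0), np.zeros(10, dtype=int))
    with pytest.raises(ConfigurationError):
        cox_fit(np.arange(10.0), np.arange(1.0, 11.0), np.ones(10, dtype=int), ties="exact")


# ---------------------------------------------------------------------------
# Schoenfeld PH test


def test_ph_test_single_covariate_global_equals_percov(rng):
    X, times, events = random_survival_data(rng, n=100)
    fit = cox_fit(X, times, events)
    per, global_p = schoenfeld_ph_test(fit, X, times, events)
    assert per[0] == pytest.approx(global_p, abs=1e-12)


def test_ph_test_matches_lifelines(rng):
    for _ in range(5):
        p = int(rng.integers(1, 3))
        X, times, events = random_survival_data(rng, n=90, p=p)
        if events.sum() < 5:
            continue
        fit = cox_fit(X, times, events)
        per, _ = schoenfeld_ph_test(fit, X, times, events)
        df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
        df["T"], df["E"] = times, events
        cph = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-12})
        ref = proportional_hazard_test(cph, df, time_transform="km")
        assert np.allclose(np.sort(per), np.sort(np.atleast_1d(ref.p_value)), atol=1e-6)


def test_ph_test_null_pvalues_uniform():
    # under proportional hazards the test p-values should be ~Uniform(0,1)
    rng = np.random.default_rng(77)
    pvals = []
    for _ in range(200):
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(5 * np.exp(-0.4 * x))
        c = rng.exponential(10, n)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
        fit = cox_fit(x, times, events)
        per, _ = schoenfeld_ph_test(fit, x, times, events)
        pvals.append(per[0])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_ph_test_detects_reversing_hazard():
    # hazard ratio reverses at t=15: strong violation
    rng = np.random.default_rng(5)
    n = 2000
    g = rng.integers(0, 2, n)
    h1 = np.where(g == 1, 0.2, 0.02)  # before t=15
    h2 = np.where(g == 1, 0.02, 0.2)  # after
    t1 = rng.exponential(1 / h1)
    t = np.where(t1 < 15, t1, 15 + rng.exponential(1 / h2))
    times = np.minimum(t, 30)
    events = (t <= 30).astype(int)
    fit = cox_fit(g.astype(float), times, events)
    per, global_p = schoenfeld_ph_test(fit, g.astype(float), times, events)
    assert per[0] < 0.01
    assert global_p < 0.01


def test_ph_test_requires_events():
    fit = cox_fit(
        np.arange(6.0), [1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0]
    )
    with pytest.raises(DegenerateDataError):
        schoenfeld_ph_test(fit, np.arange(6.0), [1, 2, 3], [1, 1, 0])
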