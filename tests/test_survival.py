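"""Survival-core checks against hand calculations and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnmbc.survival import (
    bh_adjust,
    bootstrap_ci,
    concordance,
    cox_fit,
    km_estimate,
    logrank_test,
)


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "times, events, points",
    [
        ([5, 10], [1, 1], {5: 0.5, 10: 0.0}),
        ([3, 5, 7], [1, 0, 1], {3: 2 / 3, 5: 2 / 3, 7: 0.0}),
        ([2, 2, 4], [1, 1, 0], {2: 1 / 3, 4: 1 / 3}),
    ],
)
def test_km_product_limit_by_hand(times, events, points):
    curve = km_estimate(times, events)
    for t, s in points.items():
        assert curve.survival_at(t) == pytest.approx(s)


def test_km_all_censored_is_flat():
    curve = km_estimate([1, 2, 3], [0, 0, 0])
    assert curve.times.size == 0
    assert curve.survival_at(3) == 1.0


def test_km_events_precede_censorings_at_ties():
    # censored subject at t=2 is still at risk for the death at t=2
    curve = km_estimate([2, 2, 5], [1, 0, 1])
    assert curve.survival_at(2) == pytest.approx(2 / 3)


def test_km_matches_lifelines(small_cohort):
    lifelines = pytest.importorskip("lifelines")
    df = small_cohort.df
    kmf = lifelines.KaplanMeierFitter().fit(df["time_months"], df["event_os"])
    curve = km_estimate(df["time_months"], df["event_os"])
    for t in [1, 6, 12, 24, 60, 119]:
        assert curve.survival_at(t) == pytest.approx(
            float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
        )


def test_km_rejects_bad_input():
    with pytest.raises(ValueError):
        km_estimate([], [])
    with pytest.raises(ValueError):
        km_estimate([-1, 2], [1, 1])


@settings(max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(1, 30), st.integers(0, 1)), min_size=1, max_size=40
    )
)
def test_km_monotone_and_bounded(data):
    times = [t for t, _ in data]
    events = [e for _, e in data]
    curve = km_estimate(times, events)
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert np.all((curve.survival >= -1e-12) & (curve.survival <= 1 + 1e-12))
    if all(e == 1 for e in events):
        assert curve.survival_at(max(times)) == pytest.approx(0.0)


# --------------------------------------------------------------------------
# Log-rank
# --------------------------------------------------------------------------

def _logrank_2group_oracle(times, events, groups):
    """Direct textbook O-E / hypergeometric-variance enumeration."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == "A")).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == "A")).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def test_logrank_identical_groups_is_null():
    t = [1, 2, 3, 4, 5, 6]
    e = [1, 1, 0, 1, 1, 0]
    res = logrank_test(t + t, e + e, ["A"] * 6 + ["B"] * 6)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_two_groups_matches_enumeration_oracle():
    times = [1, 2, 3, 4]
    events = [1, 1, 1, 1]
    groups = ["A", "A", "B", "B"]
    res = logrank_test(times, events, groups)
    assert res.df == 1
    assert res.chi2 == pytest.approx(
        _logrank_2group_oracle(times, events, groups), rel=1e-12
    )


def test_logrank_matches_lifelines_three_groups(small_cohort):
    lifelines_stats = pytest.importorskip("lifelines.statistics")
    df = small_cohort.df
    ours = logrank_test(df["time_months"], df["event_os"], df["arm"])
    ref = lifelines_stats.multivariate_logrank_test(
        df["time_months"], df["arm"], df["event_os"]
    )
    assert ours.df == 2
    assert ours.chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
    assert ours.p == pytest.approx(ref.p_value, rel=1e-8)


def test_logrank_single_group_rejected():
    with pytest.raises(ValueError):
        logrank_test([1, 2], [1, 1], ["A", "A"])


# --------------------------------------------------------------------------
# Benjamini-Hochberg
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw, expected",
    [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.005, 0.01, 0.03, 0.04], [0.02, 0.02, 0.04, 0.04]),
    ],
)
def test_bh_step_up_by_hand(raw, expected):
    assert bh_adjust(raw) == pytest.approx(expected)


def test_bh_preserves_input_order():
    out = bh_adjust([0.04, 0.005, 0.03, 0.01])
    assert out == pytest.approx([0.04, 0.02, 0.04, 0.02])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@settings(max_examples=80, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
def test_bh_dominates_input_and_preserves_ranking(p):
    adj = bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_agrees_with_statsmodels(rng):
    sm_multitest = pytest.importorskip("statsmodels.stats.multitest")
    p = rng.random(40)
    ref = sm_multitest.multipletests(p, method="fdr_bh")[1]
    assert bh_adjust(p) == pytest.approx(ref, abs=1e-12)


# --------------------------------------------------------------------------
# Cox partial likelihood
# --------------------------------------------------------------------------

def _cox_1d_partial_loglik(beta, x, times, events):
    """Brute-force 1-D partial log-likelihood (Breslow; no tied event times)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def test_cox_four_subject_example_matches_grid_oracle():
    times = np.array([1.0, 2.0, 3.0, 4.0])
    events = np.array([1, 1, 1, 1])
    x = np.array([1.0, 0.0, 1.0, 0.0])
    grid = np.linspace(-4, 4, 160001)
    lls = [_cox_1d_partial_loglik(b, x, times, events) for b in grid]
    oracle_beta = grid[int(np.argmax(lls))]
    fit = cox_fit(x[:, None], times, events, ties="breslow")
    assert fit.converged
    assert fit.coef[0] == pytest.approx(oracle_beta, abs=1e-4)
    assert fit.loglik == pytest.approx(max(lls), abs=1e-8)


def test_cox_monotone_likelihood_flagged():
    # the x=1 subjects all die first: the partial likelihood increases
    # monotonically in beta, so no finite maximizer exists
    times = np.array([1.0, 2.0, 3.0, 4.0])
    events = np.array([1, 1, 1, 1])
    x = np.array([1.0, 1.0, 0.0, 0.0])
    fit = cox_fit(x[:, None], times, events, ties="breslow")
    assert not fit.converged
    assert "monotone" in fit.message


def test_cox_mirrored_groups_give_zero_coefficient():
    # the two groups share an identical survival experience
    times = [1, 2, 3, 4, 1, 2, 3, 4]
    events = [1, 1, 1, 0, 1, 1, 1, 0]
    x = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
    fit = cox_fit(x[:, None], times, events)
    assert abs(fit.coef[0]) < 1e-6


def test_cox_single_subject_rejected():
    with pytest.raises(ValueError):
        cox_fit(np.array([[1.0]]), [5.0], [1])


def test_cox_constant_column_rejected():
    with pytest.raises(ValueError):
        cox_fit(np.ones((5, 1)), [1, 2, 3, 4, 5], [1, 1, 1, 0, 1])


def test_cox_efron_breslow_agree_without_ties(rng):
    n = 120
    x = rng.normal(size=(n, 2))
    times = rng.exponential(10, n) * np.exp(-0.5 * x[:, 0])
    events = (rng.random(n) < 0.7).astype(int)
    events[0] = 1
    fe = cox_fit(x, times, events, ties="efron")
    fb = cox_fit(x, times, events, ties="breslow")
    assert fe.coef == pytest.approx(fb.coef, abs=1e-6)


def test_cox_matches_lifelines_on_tied_data(small_cohort):
    lifelines = pytest.importorskip("lifelines")
    df = small_cohort.df[["time_months", "event_os"]].copy()
    df["ns"] = (small_cohort.df["arm"] == "NS").astype(float)
    df["sc"] = (small_cohort.df["arm"] == "SC").astype(float)
    cph = lifelines.CoxPHFitter().fit(df, "time_months", "event_os")
    fit = cox_fit(
        df[["ns", "sc"]].to_numpy(), df["time_months"], df["event_os"], ties="efron"
    )
    assert fit.coef == pytest.approx(cph.params_.to_numpy(), abs=2e-6)
    assert fit.se == pytest.approx(cph.standard_errors_.to_numpy(), abs=2e-6)


def test_cox_hazard_ratio_fields_consistent(recovery_cohort):
    df = recovery_cohort.df
    x = (df["arm"] == "NS").to_numpy(float)[:, None]
    fit = cox_fit(x, df["time_months"], df["event_os"])
    assert fit.hr == pytest.approx(np.exp(fit.coef))
    assert np.all(fit.ci95[:, 0] <= fit.hr)
    assert np.all(fit.hr <= fit.ci95[:, 1])
    assert np.all((fit.p >= 0) & (fit.p <= 1))


# --------------------------------------------------------------------------
# Concordance
# --------------------------------------------------------------------------

def naive_concordance(times, events, risks):
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not comparable:
                continue
            den += 1
            if risks[i] > risks[j]:
                num += 1
            elif risks[i] == risks[j]:
                num += 0.5
    return num / den, int(den)


def test_concordance_perfect_and_tied():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [1, 1, 1, 1]
    assert concordance(t, e, [4.0, 3.0, 2.0, 1.0]).c == 1.0
    assert concordance(t, e, [0.0, 0.0, 0.0, 0.0]).c == 0.5


def test_concordance_no_comparable_pairs_rejected():
    with pytest.raises(ValueError):
        concordance([5.0, 5.0], [1, 1], [1.0, 2.0])


def test_concordance_equals_exhaustive_oracle(rng):
    for _ in range(60):
        n = int(rng.integers(3, 31))
        t = rng.integers(1, 12, n).astype(float)
        e = rng.integers(0, 2, n)
        r = rng.choice([0.0, 0.5, 1.0, 2.0], n)
        if not ((e == 1) & (t < t.max())).any():
            continue
        expected_c, expected_pairs = naive_concordance(t, e, r)
        res = concordance(t, e, r)
        assert res.c == pytest.approx(expected_c, abs=1e-12)
        assert res.n_pairs == expected_pairs


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------

def test_bootstrap_constant_statistic_zero_width():
    lo, hi = bootstrap_ci(np.arange(50.0), lambda x: 3.14, resamples=50, seed=0)
    assert lo == hi == pytest.approx(3.14)


def test_bootstrap_reproducible_and_sane():
    data = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    a = bootstrap_ci(data, np.mean, resamples=1000, seed=42)
    b = bootstrap_ci(data, np.mean, resamples=1000, seed=42)
    assert a == b
    assert a[0] <= 3.0 <= a[1]
    assert 1.0 <= a[0] and a[1] <= 5.0


def test_bootstrap_gives_up_on_undefined_statistic():
    def bad(_):
        raise ValueError("always undefined")

    with pytest.raises(RuntimeError):
        bootstrap_ci(np.arange(10.0), bad, resamples=5, seed=0)
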