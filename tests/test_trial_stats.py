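"""Statistics validated against hand calculations, brute-force enumeration,
and independent implementations (scipy, lifelines)."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ectplan import (
    ContingencyTable2x2,
    SurvivalSample,
    fisher_exact_two_sided,
    kaplan_meier,
    log_rank,
    mann_whitney,
    one_way_anova,
    response_rate_summary,
    welch_t_test,
)


# --- Fisher ------------------------------------------------------------------


def brute_force_fisher(a, b, c, d):
    """Independent oracle: enumerate every table with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    probs = []
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = (
            Fraction(math.comb(r1, k))
            * Fraction(math.comb(r2, c1 - k))
            / Fraction(math.comb(n, c1))
        )
        probs.append((k, p))
    p_obs = dict(probs)[a]
    return float(sum(p for _, p in probs if p <= p_obs))


def test_reconstructed_trial_table_prints_0067():
    p = fisher_exact_two_sided(ContingencyTable2x2(36, 1, 12, 3))
    assert round(p, 3) == 0.067
    assert p == pytest.approx(brute_force_fisher(36, 1, 12, 3), rel=1e-12)


@pytest.mark.parametrize(
    "table,expected",
    [
        ((1, 1, 1, 1), 1.0),
        ((5, 0, 0, 5), 0.00794),
    ],
)
def test_fisher_known_values(table, expected):
    assert fisher_exact_two_sided(ContingencyTable2x2(*table)) == pytest.approx(
        expected, rel=5e-3
    )


def test_fisher_empty_margin_convention():
    assert fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 4)) == 1.0


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    a=st.integers(0, 15),
    b=st.integers(0, 15),
    c=st.integers(0, 15),
    d=st.integers(0, 15),
)
def test_fisher_matches_enumeration_and_scipy(a, b, c, d):
    if a + b + c + d == 0:
        return
    table = ContingencyTable2x2(a, b, c, d)
    p = fisher_exact_two_sided(table)
    assert 0.0 <= p <= 1.0
    if table.has_empty_margin:
        assert p == 1.0
        return
    assert p == pytest.approx(brute_force_fisher(a, b, c, d), rel=1e-9)
    _, p_scipy = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    assert p == pytest.approx(p_scipy, rel=1e-6, abs=1e-12)


# --- response rates ----------------------------------------------------------


def test_trial_response_rate_arithmetic():
    thin = response_rate_summary({"CR": 26, "PR": 10, "SD": 1}, n=37)
    assert (thin["CR"], thin["PR"], thin["SD"], thin["OR"]) == (70.3, 27.0, 2.7, 97.3)
    std = response_rate_summary({"CR": 6, "PR": 6, "SD": 2, "NE": 1}, n=15)
    assert (std["CR"], std["PR"], std["SD"], std["OR"]) == (40.0, 40.0, 13.3, 80.0)


def test_response_rate_all_not_evaluable():
    out = response_rate_summary({"NE": 10}, n=10)
    assert out["OR"] == 0.0 and out["NE"] == 100.0


def test_response_counts_exceeding_n_rejected():
    with pytest.raises(ValueError):
        response_rate_summary({"CR": 10, "PR": 10}, n=15)


# --- Mann-Whitney ------------------------------------------------------------


def test_mann_whitney_exact_small_sample():
    out = mann_whitney([1, 2], [3, 4])
    assert out["U"] == 0.0
    assert out["p"] == pytest.approx(1 / 3, rel=1e-12)


def test_mann_whitney_identical_samples():
    assert mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])["p"] == 1.0


def test_mann_whitney_exact_matches_scipy():
    rng = np.random.default_rng(11)
    for _ in range(20):
        x = rng.permutation(np.arange(20.0))[:6]
        rest = np.setdiff1d(np.arange(20.0), x)
        y = rng.permutation(rest)[:9]
        ours = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours["p"] == pytest.approx(ref.pvalue, rel=1e-9)


def test_mann_whitney_tied_grades_match_scipy_asymptotic():
    rng = np.random.default_rng(5)
    x = rng.integers(1, 6, size=15).astype(float)
    y = rng.integers(1, 4, size=37).astype(float)
    ours = mann_whitney(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert ours["p"] == pytest.approx(ref.pvalue, rel=1e-6)


def test_mann_whitney_separates_trial_like_anorexia_grades():
    """Anorexia-grade contrast at the trial's arm sizes is overwhelmingly
    significant across seeded synthetic replicates."""
    rng = np.random.default_rng(2)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        std = rng.choice([1, 2, 3, 4, 5], size=15, p=[0.10, 0.20, 0.30, 0.30, 0.10])
        thin = rng.choice([1, 2, 3], size=37, p=[0.75, 0.20, 0.05])
        hits += mann_whitney(std, thin)["p"] < 1e-3
    assert hits / n_rep >= 0.90


# --- Kaplan-Meier ------------------------------------------------------------


def test_product_limit_no_censoring():
    km = kaplan_meier(SurvivalSample((1.0, 2.0, 3.0), (True, True, True)))
    assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
    assert km.median == 2.0


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(3)
    times = rng.exponential(100.0, size=40) + 1.0
    km = kaplan_meier(SurvivalSample(tuple(times), (True,) * 40))
    for t in (50.0, 100.0, 200.0):
        assert km.survival_at(t) == pytest.approx(np.mean(times > t))


def test_km_all_censored():
    km = kaplan_meier(SurvivalSample((5.0, 8.0), (False, False)))
    assert km.event_times.size == 0
    assert km.median is None
    assert km.survival_at(100.0) == 1.0


def test_km_single_event_drops_to_zero():
    km = kaplan_meier(SurvivalSample((7.0,), (True,)))
    assert km.survival == pytest.approx([0.0])
    assert km.median == 7.0


def test_km_hand_computed_with_censoring():
    # times 1 (event), 2 (censored), 3 (event): S = 2/3 then 0; median 3
    km = kaplan_meier(SurvivalSample((1.0, 2.0, 3.0), (True, False, True)))
    assert km.survival == pytest.approx([2 / 3, 0.0])
    assert km.median == 3.0


def test_km_matches_lifelines():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(9)
    times = rng.exponential(300.0, size=60) + 1.0
    events = rng.random(60) < 0.7
    km = kaplan_meier(SurvivalSample(tuple(times), tuple(events)))
    kmf = lifelines.KaplanMeierFitter().fit(times, events)
    for t, s in zip(km.event_times, km.survival):
        assert s == pytest.approx(
            float(kmf.survival_function_at_times(t).iloc[0]), rel=1e-9
        )
    assert km.median == pytest.approx(float(kmf.median_survival_time_))


# --- log-rank ----------------------------------------------------------------


def test_log_rank_identical_samples():
    s = SurvivalSample((1.0, 2.0, 3.0, 4.0), (True, True, False, True))
    out = log_rank(s, s)
    assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
    assert out["p"] == pytest.approx(1.0)


def test_log_rank_symmetric_in_group_order():
    rng = np.random.default_rng(4)
    a = SurvivalSample(tuple(rng.exponential(100, 20) + 1), (True,) * 20)
    b = SurvivalSample(tuple(rng.exponential(300, 25) + 1), (True,) * 25)
    assert log_rank(a, b)["chi2"] == pytest.approx(log_rank(b, a)["chi2"], rel=1e-12)
    assert log_rank(a, b)["chi2"] >= 0.0


def test_log_rank_requires_events():
    a = SurvivalSample((1.0, 2.0), (False, False))
    with pytest.raises(ValueError, match="no observed events"):
        log_rank(a, a)


def test_log_rank_matches_lifelines():
    lifelines_stats = pytest.importorskip("lifelines.statistics")
    rng = np.random.default_rng(6)
    t1 = rng.exponential(200, 30) + 1
    t2 = rng.exponential(500, 35) + 1
    e1 = rng.random(30) < 0.8
    e2 = rng.random(35) < 0.8
    ours = log_rank(
        SurvivalSample(tuple(t1), tuple(e1)), SurvivalSample(tuple(t2), tuple(e2))
    )
    ref = lifelines_stats.logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    assert ours["chi2"] == pytest.approx(ref.test_statistic, rel=1e-9)
    assert ours["p"] == pytest.approx(ref.p_value, rel=1e-9)


def test_log_rank_power_trial_sized_similar_groups():
    """Arms with medians 611 vs 520 days at n = 37/15 mostly look the same."""
    rng = np.random.default_rng(7)
    ln2 = math.log(2)
    nonsig = 0
    n_rep = 200
    for _ in range(n_rep):
        t1 = np.clip(rng.exponential(611 / ln2, 37), 1, None)
        t2 = np.clip(rng.exponential(520 / ln2, 15), 1, None)
        s1 = SurvivalSample(tuple(np.minimum(t1, 1003)), tuple(t1 <= 1003))
        s2 = SurvivalSample(tuple(np.minimum(t2, 1003)), tuple(t2 <= 1003))
        nonsig += log_rank(s1, s2)["p"] > 0.05
    assert nonsig / n_rep > 0.5


def test_log_rank_power_hazard_ratio_four():
    """A four-fold hazard contrast at n = 26 per arm is almost always detected."""
    rng = np.random.default_rng(8)
    ln2 = math.log(2)
    sig = 0
    n_rep = 200
    for _ in range(n_rep):
        t1 = np.clip(rng.exponential(600 / ln2, 26), 1, None)
        t2 = np.clip(rng.exponential(150 / ln2, 26), 1, None)
        s1 = SurvivalSample(tuple(np.minimum(t1, 1003)), tuple(t1 <= 1003))
        s2 = SurvivalSample(tuple(np.minimum(t2, 1003)), tuple(t2 <= 1003))
        sig += log_rank(s1, s2)["p"] < 0.05
    assert sig / n_rep >= 0.90


# --- t-test / ANOVA ----------------------------------------------------------


def test_welch_identical_groups():
    x = [1.0, 2.0, 3.0, 4.0]
    assert welch_t_test(x, x)["p"] == pytest.approx(1.0)


def test_welch_matches_scipy():
    rng = np.random.default_rng(10)
    x = rng.normal(0, 1, 25)
    y = rng.normal(0.5, 2, 30)
    ours = welch_t_test(x, y)
    ref = sps.ttest_ind(x, y, equal_var=False)
    assert ours["t"] == pytest.approx(ref.statistic, rel=1e-12)
    assert ours["p"] == pytest.approx(ref.pvalue, rel=1e-9)


def test_anova_two_groups_equals_squared_t():
    rng = np.random.default_rng(12)
    x = rng.normal(0, 1, 20)
    y = rng.normal(1, 1, 20)
    f = one_way_anova([x, y])["F"]
    t = sps.ttest_ind(x, y, equal_var=True).statistic
    assert f == pytest.approx(t**2, rel=1e-9)


def test_large_shift_is_significant():
    rng = np.random.default_rng(13)
    x = rng.normal(0, 1, 200)
    y = rng.normal(2, 1, 200)
    assert welch_t_test(x, y)["p"] < 1e-3
    assert one_way_anova([x, y])["p"] < 1e-3


def test_degenerate_variance_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        welch_t_test([1.0, 1.0, 1.0], [1.0, 1.0])
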