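import numpy as np
import pandas as pd
import pytest

from atrcn import (
    RiskScores,
    chisq_association,
    concordance_index,
    evaluate_risk_scores,
    logrank_test,
    median_split,
)
from atrcn.evaluation import RiskGroups

from conftest import make_survival, random_survival


def brute_force_c_index(scores, times, events):
    """Oracle: explicit double loop applying Harrell's permissibility rules."""
    num, den = 0.0, 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            permissible = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not permissible:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_perfectly_ordered_scores():
    s = make_survival([1.0, 2.0, 3.0], [1, 1, 1])
    assert concordance_index(np.array([3.0, 2.0, 1.0]), s) == 1.0
    assert concordance_index(np.array([1.0, 2.0, 3.0]), s) == 0.0


def test_matches_brute_force_enumeration(rng):
    for _ in range(100):
        n = int(rng.integers(3, 13))
        t = np.round(rng.exponential(5.0, n), 0) + 1  # coarse -> many ties
        e = rng.integers(0, 2, n)
        sc = np.round(rng.normal(size=n), 1)  # occasional score ties
        if not ((e == 1) & (t < t.max())).any():
            e[np.argmin(t)] = 1
        s = make_survival(t, e)
        assert concordance_index(sc, s) == pytest.approx(
            brute_force_c_index(sc, t, e)
        )


def test_complement_identity_without_ties(rng):
    for _ in range(20):
        n = 12
        s = random_survival(rng, n)
        sc = rng.normal(size=n)  # continuous: no ties a.s.
        assert concordance_index(sc, s) + concordance_index(-sc, s) == pytest.approx(1.0)


def test_invariant_under_monotone_transform(rng):
    s = random_survival(rng, 30)
    sc = rng.normal(size=30)
    c = concordance_index(sc, s)
    assert concordance_index(np.exp(2.0 * sc) + 5, s) == pytest.approx(c)


def test_no_permissible_pairs_rejected():
    s = make_survival([5.0, 5.0], [1, 1])  # tied events: no ordering possible
    with pytest.raises(ValueError):
        concordance_index(np.array([1.0, 2.0]), s)


# ---------------------------------------------------------------------------
# median split
# ---------------------------------------------------------------------------

def test_median_split_even_n():
    scores = RiskScores(list("abcd"), np.array([1.0, 2.0, 3.0, 4.0]))
    g = median_split(scores)
    assert g.threshold == 2.5
    assert dict(zip(g.sample_ids, g.group)) == {
        "a": "low", "b": "low", "c": "high", "d": "high"
    }


def test_median_split_odd_n_median_goes_low():
    g = median_split(RiskScores(list("abc"), np.array([1.0, 2.0, 3.0])))
    assert dict(zip(g.sample_ids, g.group))["b"] == "low"


def test_median_split_partitions(rng):
    scores = RiskScores([str(i) for i in range(11)], rng.normal(size=11))
    g = median_split(scores)
    assert set(g.group) == {"high", "low"}
    assert len(g.group) == 11


def test_constant_scores_rejected():
    with pytest.raises(ValueError):
        median_split(RiskScores(list("ab"), np.array([1.0, 1.0])))


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _groups(labels):
    return RiskGroups([str(i) for i in range(len(labels))],
                      np.array(labels), threshold=0.0)


def test_identical_groups_null_identity():
    t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    e = [1, 1, 0, 1, 1, 0]
    stat, p = logrank_test(_groups(["high"] * 3 + ["low"] * 3), make_survival(t, e))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_observed_minus_expected_oracle():
    # small worked instance, all uncensored, no ties
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    e = np.ones(6, int)
    labels = ["high", "low", "high", "low", "high", "low"]
    stat, p = logrank_test(_groups(labels), make_survival(t, e))

    # oracle: explicit at-risk table per event time for the "high" group
    obs_minus_exp, var = 0.0, 0.0
    at_risk = list(zip(t, labels))
    for i, (ti, gi) in enumerate(zip(t, labels)):
        n_total = sum(1 for tj, _ in at_risk if tj >= ti)
        n_high = sum(1 for tj, gj in at_risk if tj >= ti and gj == "high")
        expected = n_high / n_total
        obs_minus_exp += (1 if gi == "high" else 0) - expected
        if n_total > 1:
            var += expected * (1 - expected)  # hypergeometric, one event per time
    expected_stat = obs_minus_exp**2 / var
    assert stat == pytest.approx(expected_stat, rel=1e-9)


def test_logrank_detects_strong_separation(rng):
    """Hazard ratio 3 between groups, n=200: significant in >= 95% of runs."""
    hits = 0
    n_runs = 60
    for seed in range(n_runs):
        r = np.random.default_rng(seed)
        n = 100
        t_high = r.exponential(1.0 / 3.0, n)
        t_low = r.exponential(1.0, n)
        s = make_survival(np.r_[t_high, t_low] + 1e-9, np.ones(2 * n, int))
        _, p = logrank_test(_groups(["high"] * n + ["low"] * n), s)
        hits += p < 0.05
    assert hits >= 0.95 * n_runs


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        logrank_test(_groups(["high", "high"]), make_survival([1.0, 2.0], [1, 1]))


# ---------------------------------------------------------------------------
# chi-square association
# ---------------------------------------------------------------------------

def test_balanced_table_independence():
    groups = _groups(["high"] * 20 + ["low"] * 20)
    cov = (["a"] * 10 + ["b"] * 10) * 2
    stat, p, df = chisq_association(groups, pd.Series(cov))
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    assert df == 1


def test_2x2_matches_hand_formula():
    # contingency [[20, 10], [10, 20]]
    groups = _groups(["high"] * 30 + ["low"] * 30)
    cov = ["a"] * 20 + ["b"] * 10 + ["a"] * 10 + ["b"] * 20
    stat, p, df = chisq_association(groups, pd.Series(cov))
    # oracle: direct sum of (O-E)^2/E with all margins 30
    expected = sum((o - 15.0) ** 2 / 15.0 for o in (20, 10, 10, 20))
    assert stat == pytest.approx(expected)
    assert df == 1


def test_continuous_covariate_quartile_binned(rng):
    groups = _groups(["high"] * 40 + ["low"] * 40)
    stat, p, df = chisq_association(groups, pd.Series(rng.normal(size=80)))
    assert df == 3  # 2 x 4 table after quartile binning


def test_single_category_rejected():
    groups = _groups(["high", "low"])
    with pytest.raises(ValueError):
        chisq_association(groups, pd.Series(["x", "x"]))


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def test_report_bundles_all_statistics(rng):
    n = 60
    s = random_survival(rng, n)
    scores = RiskScores(list(s.sample_ids), rng.normal(size=n))
    cov = pd.DataFrame({"stage": rng.choice(["I", "II", "III"], n)})
    rep = evaluate_risk_scores(scores, s, per_fold_c=[0.6, 0.7], covariates=cov)
    assert 0.0 <= rep.c_index <= 1.0
    assert 0.0 < rep.logrank_p <= 1.0
    assert rep.cv_mean_c == pytest.approx(0.65)
    assert rep.covariate_tests[0][0] == "stage"
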