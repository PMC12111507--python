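"""Exact and classical group-comparison tests on small-cohort tables."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from eopmeth.cohortstats import (SummaryStats, chi2_or_fisher,
                                 fisher_exact_2x2, mann_whitney,
                                 t_test_from_summary, table1_report)


def test_t_identical_summaries_null():
    s = SummaryStats(10, 5.0, 1.0)
    t, df, p = t_test_from_summary(s, s)
    assert t == 0.0 and p == pytest.approx(1.0)


def test_t_welch_closed_form():
    # independent closed-form check of the Welch statistic and df
    t, df, p = t_test_from_summary(
        SummaryStats(12, 9.3, 1.96), SummaryStats(11, 7.2, 2.05), "welch"
    )
    assert t == pytest.approx(2.51, abs=0.01)
    assert df == pytest.approx(20.6, abs=0.1)


def test_t_from_summary_equals_raw_data_tests():
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 1, 14), rng.normal(0.8, 1.4, 9)
    sx = SummaryStats(len(x), x.mean(), x.std(ddof=1))
    sy = SummaryStats(len(y), y.mean(), y.std(ddof=1))
    for variant, equal_var in (("welch", False), ("pooled", True)):
        t, _, p = t_test_from_summary(sx, sy, variant)
        ref = stats.ttest_ind(x, y, equal_var=equal_var)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


def test_t_validation():
    with pytest.raises(ValueError):
        SummaryStats(1, 0.0, 1.0)
    with pytest.raises(ValueError):
        t_test_from_summary(SummaryStats(5, 1.0, 0.0), SummaryStats(5, 1.0, 0.0))


def exact_mw_p(x, y):
    """Brute-force two-sided Mann-Whitney by enumerating all arrangements."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    def u_of(subset):
        r1 = sum(ranks[v] for v in subset)
        return r1 - n1 * (n1 + 1) / 2
    u_obs = u_of(x)
    n2 = len(y)
    mid = n1 * n2 / 2
    count = sum(
        1 for c in combinations(pooled, n1)
        if abs(u_of(c) - mid) >= abs(u_obs - mid) - 1e-12
    )
    return count / comb(len(pooled), n1)


def test_mann_whitney_exact_small_sample():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)
    assert p == pytest.approx(exact_mw_p([1, 2, 3], [4, 5, 6]))


def test_mann_whitney_matches_enumeration_oracle():
    rng = np.random.default_rng(1)
    x = rng.permutation(np.arange(11.0))[:5]
    y = np.setdiff1d(np.arange(11.0), x)[:6]
    _, p = mann_whitney(x, y)
    assert p == pytest.approx(exact_mw_p(list(x), list(y)), abs=1e-12)


def test_mann_whitney_symmetry_and_identity():
    x = [3.0, 1.0, 4.0, 1.5]
    y = [1.5, 4.0, 3.0, 1.0]
    _, p = mann_whitney(x, y)
    assert p == pytest.approx(1.0, abs=1e-9)
    a, b = [1.0, 5.0, 2.0], [4.0, 8.0, 0.5, 9.0]
    assert mann_whitney(a, b)[1] == pytest.approx(mann_whitney(b, a)[1])


@pytest.mark.parametrize(
    "table,expected",
    [
        ([[7, 5], [1, 10]], 0.027),   # psychiatric admissions
        ([[10, 2], [4, 7]], 0.036),   # anxiety and stress disorders
        ([[1, 11], [4, 7]], 0.155),   # neurodevelopmental disorders
        ([[4, 8], [0, 11]], 0.093),   # eating disorder
        ([[6, 6], [7, 4]], 0.680),    # gender
        ([[5, 7], [5, 6]], 1.0),      # conduct disorders
    ],
)
def test_fisher_reproduces_printed_cohort_pvalues(table, expected):
    assert round(fisher_exact_2x2(table), 3) == expected


def test_fisher_matches_scipy_and_monotone_diagonal():
    rng = np.random.default_rng(2)
    for _ in range(50):
        t = rng.integers(0, 15, (2, 2))
        if t.sum() == 0:
            continue
        assert fisher_exact_2x2(t) == pytest.approx(
            stats.fisher_exact(t)[1], rel=1e-9
        )
    prev = 2.0
    for k in (1, 2, 3, 5, 8):
        p = fisher_exact_2x2([[k, 0], [0, k]])
        assert p < prev
        prev = p


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30))
def test_fisher_hypergeometric_probabilities_sum_to_one(r1, r2, c1):
    # distribution over all tables with fixed margins is a proper pmf
    n = r1 + r2
    c1 = min(c1, n)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    total = sum(
        Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))
        for k in range(lo, hi + 1)
    )
    assert total == 1
    # and the implementation's two-sided p never exceeds 1, >= one-sided
    a = (lo + hi) // 2
    table = [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
    p2 = fisher_exact_2x2(table)
    p1 = min(fisher_exact_2x2(table, "less"), fisher_exact_2x2(table, "greater"))
    assert 0 < p2 <= 1 + 1e-12
    assert p2 >= p1 - 1e-12


def test_fisher_validation():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[0, 0], [0, 0]])
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


def test_chi2_or_fisher_branching():
    p, method = chi2_or_fisher([[10, 2], [4, 7]])
    assert method == "fisher" and round(p, 3) == 0.036
    p, method = chi2_or_fisher([[50, 50], [50, 50]])
    assert method == "chi2" and p == pytest.approx(1.0)


def test_table1_report_flags_planted_difference():
    rng = np.random.default_rng(3)
    n = 40
    sheet = pd.DataFrame(
        {
            "group": np.repeat([1, 0], n // 2),
            "score": np.r_[rng.normal(10, 1, n // 2), rng.normal(5, 1, n // 2)],
            "noise": rng.normal(size=n),
            "adm": rng.poisson(1.0, n),
            "flag": rng.integers(0, 2, n),
        },
        index=[f"S{i}" for i in range(n)],
    )
    rep = table1_report(
        sheet,
        [("score", "continuous"), ("noise", "continuous"), ("adm", "count"),
         ("flag", "categorical"), ("absent", "continuous")],
    ).set_index("variable")
    assert rep.loc["score", "significant"]
    assert not rep.loc["noise", "significant"]
    assert rep.loc["absent", "test"] == "missing"


def test_table1_percentages_within_group():
    sheet = pd.DataFrame(
        {
            "group": [1] * 12 + [0] * 11,
            "admit": [1] * 7 + [0] * 5 + [1] * 1 + [0] * 10,
        }
    )
    rep = table1_report(sheet, [("admit", "categorical")])
    assert rep["group1"].iloc[0] == "7 (58)"
    assert rep["group0"].iloc[0] == "1 (9)"
    assert round(rep["p"].iloc[0], 3) == 0.027


def test_table1_requires_two_populated_groups():
    sheet = pd.DataFrame({"group": [1, 0, 0, 0], "x": [1.0, 2, 3, 4]})
    with pytest.raises(ValueError):
        table1_report(sheet, [("x", "continuous")])
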