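"""Group-comparison statistics for small psychiatric cohorts.

Implements the machinery behind a classic "Table 1": two-sample t tests (from
raw data or printed summary statistics), Mann-Whitney U, Pearson chi-square
with an exact-Fisher fallback when expected counts are small, and an exact
two-sided Fisher test under the minimum-likelihood rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "t_test_from_summary",
    "mann_whitney",
    "fisher_exact_2x2",
    "chi2_or_fisher",
    "table1_report",
]


@dataclass(frozen=True)
class SummaryStats:
    """Per-group summary: sample size, mean and SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def t_test_from_summary(
    a: SummaryStats, b: SummaryStats, variant: str = "welch"
) -> tuple[float, float, float]:
    """Two-sample t test computed from summary statistics.

    ``welch`` uses the unequal-variance statistic with Satterthwaite degrees
    of freedom; ``pooled`` is the classical Student form with df = n1+n2-2.
    Returns (t, df, two-sided p).
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            raise ValueError("both groups constant and equal: t undefined")
    diff = a.mean - b.mean
    if variant == "welch":
        v1, v2 = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (a.n - 1) + v2**2 / (b.n - 1))
    else:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = a.n + b.n - 2
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def mann_whitney(x, y, method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    ``auto`` enumerates the exact null when n1*n2 <= 400 and there are no
    ties, otherwise falls back to the tie-corrected normal approximation.
    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        ties = np.unique(pooled).size < pooled.size
        method = "exact" if (x.size * y.size <= 400 and not ties) else "normal_approx"
    scipy_method = {"exact": "exact", "normal_approx": "asymptotic"}[method]
    # plain tie-corrected normal in the approximate branch (no continuity
    # correction), so equal samples give p = 1 exactly
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method=scipy_method, use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def _table_counts(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.issubdtype(t.dtype, np.integer):
        ti = np.rint(t).astype(int)
        if not np.allclose(t, ti):
            raise ValueError("counts must be integers")
        t = ti
    if t.sum() == 0:
        raise ValueError("all-zero table")
    return t


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test on a 2x2 table, exact rational arithmetic.

    The two-sided p-value follows the minimum-likelihood rule: the sum of
    hypergeometric probabilities (margins fixed) of every table whose
    probability does not exceed the observed table's. One-sided alternatives
    refer to the [0, 0] cell.
    """
    t = _table_counts(table)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    if alternative == "two-sided":
        p = sum(pk for pk in probs.values() if pk <= p_obs)
    elif alternative == "greater":
        p = sum(probs[k] for k in range(a, hi + 1))
    elif alternative == "less":
        p = sum(probs[k] for k in range(lo, a + 1))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, Fraction(1)))


def chi2_or_fisher(table) -> tuple[float, str]:
    """Pearson chi-square, switching to the exact Fisher test when any
    expected count is below 5. Returns (p, method_used) where method_used is
    ``"fisher"`` or ``"chi2"``. The chi-square branch applies no continuity
    correction.
    """
    t = _table_counts(table)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        return fisher_exact_2x2(t), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(p), "chi2"


def table1_report(sheet: pd.DataFrame, spec, group_col: str = "group") -> pd.DataFrame:
    """Group-comparison table: one row per variable in ``spec``.

    ``spec`` is a list of (variable, kind) pairs with kind in
    {"continuous", "count", "categorical"}:

    - continuous: mean +/- SD per group, Welch t test;
    - count (skewed nonnegative counts): median (min-max), Mann-Whitney;
    - categorical (binary 0/1): n (%) per group, chi-square with Fisher
      fallback.

    Variables missing from the sheet are reported with test="missing" and the
    remaining rows are still computed. Requires exactly two group levels, each
    with at least two samples.
    """
    levels = sorted(pd.unique(sheet[group_col].dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    g1 = sheet[sheet[group_col] == levels[1]]  # convention: higher level = case
    g0 = sheet[sheet[group_col] == levels[0]]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("each group needs at least two samples")
    rows = []
    for var, kind in spec:
        if var not in sheet.columns:
            rows.append(
                dict(variable=var, kind=kind, group1="", group0="",
                     p=np.nan, test="missing", significant=False)
            )
            continue
        x1 = g1[var].dropna().to_numpy(dtype=float)
        x0 = g0[var].dropna().to_numpy(dtype=float)
        if kind == "continuous":
            s1 = SummaryStats(len(x1), x1.mean(), x1.std(ddof=1))
            s0 = SummaryStats(len(x0), x0.mean(), x0.std(ddof=1))
            _, _, p = t_test_from_summary(s1, s0, "welch")
            fmt = lambda x: f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
            d1, d0, test = fmt(x1), fmt(x0), "t"
        elif kind == "count":
            _, p = mann_whitney(x1, x0)
            fmt = lambda x: f"{np.median(x):g} ({x.min():g}–{x.max():g})"
            d1, d0, test = fmt(x1), fmt(x0), "mann-whitney"
        elif kind == "categorical":
            k1, k0 = int((x1 != 0).sum()), int((x0 != 0).sum())
            tab = [[k1, len(x1) - k1], [k0, len(x0) - k0]]
            p, branch = chi2_or_fisher(tab)
            d1 = f"{k1} ({round(100 * k1 / len(x1))})"
            d0 = f"{k0} ({round(100 * k0 / len(x0))})"
            test = branch
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
        rows.append(
            dict(variable=var, kind=kind, group1=d1, group0=d0,
                 p=p, test=test, significant=bool(p < 0.05))
        )
    return pd.DataFrame(rows)
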