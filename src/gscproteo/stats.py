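"""Shared statistical primitives: BH adjustment, exact Fisher tests, row-wise t-tests."""
from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "fisher_exact_two_sided", "rowwise_ttest"]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table of counts.

    Returns ``(odds_ratio, p)``.  The p-value sums, over the hypergeometric
    support of the fixed margins, the probabilities of all tables at most as
    probable as the observed one.  Table probabilities are compared as exact
    integers (numerators over the common denominator C(n, k)), so ties are
    handled without floating-point tolerance.  The odds ratio is the sample
    odds ratio ad/bc (inf when bc = 0 with ad > 0, nan for a zero margin).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        # a zero margin: only one table is possible
        return (math.nan, 1.0)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    # integer numerators of P(X = x) over the common denominator C(n, c1)
    num = [math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(lo, hi + 1)]
    obs = num[a - lo]
    p = sum(v for v in num if v <= obs) / math.comb(n, c1)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return odds, min(1.0, p)


def rowwise_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided t-test of ``a`` (rows x replicates) against ``b``.

    Welch by default.  Rows where both groups have zero variance are degenerate
    for the t statistic; there p is set to 1 when the means agree and 0 when
    they differ, with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 replicates")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero variance in both groups; "
            "p set by mean comparison",
            RuntimeWarning,
            stacklevel=2,
        )
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
        t = np.where(degenerate, np.where(same, 0.0, np.inf), t)
    return np.asarray(t, dtype=float), np.asarray(p, dtype=float)
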