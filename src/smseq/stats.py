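"""Shared statistical primitives for the marker and association stages."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

EXACT_MAX_N = 8


def wilcoxon_exact(x, y) -> float:
    """Two-sided rank-sum P by full enumeration of rank assignments.

    Pooled values are mid-ranked (ties allowed); all C(n1+n2, n1)
    assignments of ranks to the first group are enumerated and the
    two-sided P is twice the smaller tail of the observed rank sum,
    capped at 1. Exact and deterministic; intended for small groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    total = comb(n1 + n2, n1)
    lo = hi = 0
    for idx in combinations(range(n1 + n2), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum P-value.

    Exact enumeration when both groups have <= 8 observations, else the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return wilcoxon_exact(x, y)
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def bonferroni(pvals, n_tests: int | None = None) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = len(p) if n_tests is None else n_tests
    return np.minimum(1.0, p * m)


def benjamini_hochberg(pvals) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
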