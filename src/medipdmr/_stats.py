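"""Shared rank-test machinery.

The Mann-Whitney U test is implemented here rather than delegated because
the pipeline needs an exact small-sample mode (full enumeration of group
assignments, ties handled through midranks) alongside the tie-corrected
normal approximation used for larger groups.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def _rank_average(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def mann_whitney_u(x, y, exact_max_n: int = 8):
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all group assignments when both groups have at
    most ``exact_max_n`` observations; otherwise normal approximation with
    tie correction (no continuity correction).  Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _rank_average(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    if n1 <= exact_max_n and n2 <= exact_max_n:
        # exact null: every choice of n1 pooled positions equally likely
        dev_obs = abs(u1 - mean_u)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u - mean_u) >= dev_obs - 1e-12:
                count += 1
            total += 1
        return u1, count / total
    # tie-corrected normal approximation
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return u1, 1.0
    z = (u1 - mean_u) / np.sqrt(var_u)
    return u1, min(1.0, 2.0 * stats.norm.sf(abs(z)))


def wilcoxon_signed_rank(deltas):
    """Two-sided Wilcoxon signed-rank of paired differences against zero."""
    deltas = np.asarray(deltas, dtype=float)
    nonzero = deltas[deltas != 0]
    if len(nonzero) == 0:
        return 0.0, 1.0
    res = stats.wilcoxon(nonzero, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
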