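"""Small statistical utilities used across the pipeline.

These wrap the scipy implementations behind the package's contracts
(two-sided point-probability Fisher, paired signed-rank with zero-dropping,
tie-corrected rank-sum) so callers get consistent edge-case handling.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["fisher_exact_2x2", "wilcoxon_signed_rank", "rank_sum"]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Rows are groups, columns are outcome yes/no.  Two-sided by the
    point-probability rule: the sum of probabilities of all tables with the
    same margins whose hypergeometric probability does not exceed the
    observed table's.  A zero margin makes the test degenerate; p = 1 by
    convention.
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 1.0
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def wilcoxon_signed_rank(differences: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p on paired differences.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without ties, otherwise the normal approximation with tie
    correction.  All-zero differences give p = 1.
    """
    d = np.asarray(differences, float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    ranks_tied = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not ranks_tied) else "approx"
    return float(sps.wilcoxon(d, zero_method="wilcox", method=method).pvalue)


def rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney rank-sum p with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not ties and max(len(x), len(y)) <= 25) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method=method).pvalue)
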