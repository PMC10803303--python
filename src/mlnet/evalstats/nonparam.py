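"""Rank-based hypothesis tests (scipy-backed, two-sided)."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["kruskal_wallis", "mann_whitney"]


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-square p-value.

    Degenerate input where every observation is identical has no group
    effect by construction: returns (0.0, 1.0).
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size == 0:
            raise ValueError("groups must be nonempty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration for small tie-free samples (both sizes <= 20),
    otherwise the tie-corrected normal approximation. Returns (U, p) with U
    the statistic of the first sample.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if max(x.size, y.size) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
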