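"""Rank statistics used by the single-cell analyses.

Spearman's rank correlation (average ranks for ties) and the two-sided
Mann-Whitney U test. For small samples (both groups of size <= 8) the
U null distribution is enumerated exactly over all group assignments of
the pooled ranks; larger samples use the normal approximation with tie
correction and continuity correction.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

__all__ = ["rankdata_average", "spearman_rho", "mann_whitney_u"]

EXACT_LIMIT = 8


def rankdata_average(x) -> np.ndarray:
    """1-based ranks with ties receiving their average rank."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson correlation of the average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 2:
        return float("nan")
    rx = rankdata_average(x)
    ry = rankdata_average(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return float("nan")
    return float(rx @ ry) / denom


def _u_statistic(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U of the first sample, p value). ``method`` is "exact",
    "normal" or "auto" (exact when both n <= 8). The exact p value
    enumerates every assignment of the pooled ranks to the two groups
    and counts assignments at least as extreme as observed (|U - mn/2|),
    which remains valid under ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata_average(pooled)
    u = _u_statistic(ranks[:n], n)
    mu = n * m / 2.0

    if method == "auto":
        method = "exact" if max(n, m) <= EXACT_LIMIT else "normal"

    if method == "exact":
        total = 0
        extreme = 0
        obs = abs(u - mu)
        for idx in combinations(range(n + m), n):
            uu = float(ranks[list(idx)].sum()) - n * (n + 1) / 2.0
            total += 1
            if abs(uu - mu) >= obs - 1e-12:
                extreme += 1
        return u, extreme / total

    # normal approximation with tie correction + continuity correction
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (N * (N - 1))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = math.erfc(z / math.sqrt(2.0))
    return u, min(1.0, p)
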