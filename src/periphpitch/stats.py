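"""Rank-based statistics used by the periphery comparisons.

The cross-species comparison of per-fibre F0 power is a two-sided Wilcoxon
rank-sum test.  For large samples the tie-corrected normal approximation
(without continuity correction) is used; for small pooled samples
(n1 + n2 <= 12) the two-sided p-value is computed by exhaustive enumeration of
all rank assignments, which is exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.stats import norm, rankdata

#: Largest pooled sample size for which the exact enumeration is used by default.
EXACT_LIMIT = 12


@dataclass(frozen=True)
class RankSumResult:
    """Result of a two-sided Wilcoxon rank-sum test.

    ``z`` is the tie-corrected standard-normal deviate; it is positive when the
    first sample tends to rank higher than the second.  ``method`` records
    whether ``p`` came from exact enumeration or the normal approximation.
    """

    z: float
    p: float
    n1: int
    n2: int
    method: str


def _rank_sum_z(ranks: np.ndarray, n1: int, n2: int) -> tuple[float, float, float]:
    """Return (R1, mu, sigma) for the rank-sum of the first ``n1`` entries."""
    n = n1 + n2
    r1 = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    # Tie correction: subtract sum(t^3 - t) over tie groups.
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    return r1, mu, float(np.sqrt(max(var, 0.0)))


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact p by exhaustive enumeration of rank assignments.

    Counts the fraction of all C(n1+n2, n1) assignments of the pooled
    (mid)ranks whose rank-sum deviates from its null mean by at least as much
    as the observed one.  Handles ties through midranks.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1, mu, _ = _rank_sum_z(ranks, n1, n2)
    observed_dev = abs(r1 - mu)
    n = n1 + n2
    hits = 0
    for idx in itertools.combinations(range(n), n1):
        if abs(ranks[list(idx)].sum() - mu) >= observed_dev - 1e-9:
            hits += 1
    return hits / comb(n, n1)


def rank_sum_test(x, y, method: str = "auto") -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Parameters
    ----------
    x, y : array-like
        The two samples; each must contain at least two values.
    method : {"auto", "exact", "normal"}
        "auto" uses exact enumeration when ``len(x) + len(y) <= 12`` and the
        normal approximation otherwise.

    Returns
    -------
    RankSumResult
        ``z`` follows the convention that positive values mean ``x`` ranks
        higher than ``y``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two values")
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")

    ranks = rankdata(np.concatenate([x, y]))
    r1, mu, sigma = _rank_sum_z(ranks, n1, n2)
    z = 0.0 if sigma == 0.0 else (r1 - mu) / sigma

    use_exact = method == "exact" or (method == "auto" and n1 + n2 <= EXACT_LIMIT)
    if use_exact:
        p = exact_rank_sum_p(x, y)
        how = "exact"
    else:
        p = min(1.0, 2.0 * float(norm.sf(abs(z))))
        how = "normal"
    return RankSumResult(z=float(z), p=float(p), n1=n1, n2=n2, method=how)
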