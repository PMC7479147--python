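"""Significance procedures and descriptive summaries.

Two tests cover every pairwise comparison in the analysis: the two-sided
Wilcoxon rank-sum (Mann-Whitney U) test for group comparisons and Fisher's
exact test for proportions. The rank-sum test uses the exact null
distribution for small tie-free samples (n1*n2 <= 400) and the
tie-corrected, continuity-corrected normal approximation otherwise; the
two-sided Fisher p sums hypergeometric probabilities no larger than the
observed table's (the probability-mass convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DisperseqError


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    odds_ratio: float | None = None


@dataclass
class Summary:
    mean: float
    sd: float
    sem: float
    n: int
    dispersion_defined: bool


EXACT_MAX_PRODUCT = 400


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    The reported statistic is U of the first sample. Exact enumeration is used
    when there are no ties and n1*n2 <= 400; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DisperseqError("both samples must have at least one observation")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and a.size * b.size <= EXACT_MAX_PRODUCT
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method="rank_sum_two_sided",
        n1=int(a.size),
        n2=int(b.size),
    )


def exact_proportions_test(table) -> ComparisonResult:
    """Two-sided Fisher's exact test on a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DisperseqError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise DisperseqError("table must hold non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DisperseqError("both margins must be nonzero")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return ComparisonResult(
        statistic=float(odds),
        p_value=float(p),
        method="exact_proportions_two_sided",
        n1=int(t[0].sum()),
        n2=int(t[1].sum()),
        odds_ratio=float(odds) if math.isfinite(odds) else float("inf"),
    )


def summarize(sample: Sequence[float]) -> Summary:
    """Mean, sample SD (n-1), SEM and n; dispersion undefined at n = 1."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise DisperseqError("sample must have n >= 1")
    if x.size == 1:
        return Summary(float(x[0]), float("nan"), float("nan"), 1, False)
    sd = float(x.std(ddof=1))
    return Summary(float(x.mean()), sd, sd / math.sqrt(x.size), int(x.size), True)
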