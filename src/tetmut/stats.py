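"""Statistical kernels shared by all analysis stages.

Fisher's exact test (two-sided, minimum-likelihood rule), Pearson χ²
goodness-of-fit and independence tests, and the two-sided Wilcoxon
rank-sum (Mann–Whitney) test with an exact small-sample path.
No multiple-testing correction happens here; callers decide.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "DomainError",
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_two_sided",
    "chisq_goodness_of_fit",
    "chisq_independence",
    "wilcoxon_rank_sum_two_sided",
]

# total sample size at or below which the rank-sum test enumerates the
# exact permutation null (ties force the tie-corrected normal approximation)
EXACT_RANKSUM_MAX_N = 12


class DomainError(ValueError):
    """Inputs outside the mathematical domain of a test."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise DomainError(f"counts must be non-negative integers, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise DomainError("all-zero contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    p_value: float
    statistic: Optional[float] = None
    df: Optional[int] = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact p-value.

    Sums the hypergeometric probability of every table with the observed
    margins whose probability does not exceed that of the observed table
    (the minimum-likelihood two-sided rule).
    """
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return TestResult(p_value=min(float(p), 1.0), method="fisher_exact_two_sided")


def chisq_goodness_of_fit(
    observed: Sequence[float], expected: Sequence[float]
) -> TestResult:
    """Pearson χ² against expected proportions (rescaled to the observed total)."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.ndim != 1 or obs.shape != exp.shape or len(obs) < 2:
        raise DomainError("observed and expected must be equal-length vectors, k >= 2")
    if np.any(exp <= 0):
        raise DomainError("expected counts must all be positive")
    if np.any(obs < 0):
        raise DomainError("observed counts must be non-negative")
    exp = exp * (obs.sum() / exp.sum())
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(sps.chi2.sf(stat, df))
    return TestResult(p_value=p, statistic=stat, df=df, method="chisq_goodness_of_fit")


def chisq_independence(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson χ² test of independence on an r×c count table (no continuity
    correction), df = (r−1)(c−1)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DomainError("table must be at least 2x2")
    if np.any(arr < 0):
        raise DomainError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DomainError("table has a zero margin")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult(
        p_value=float(p), statistic=float(stat), df=int(df),
        method="chisq_independence",
    )


def wilcoxon_rank_sum_two_sided(
    x: Sequence[float], y: Sequence[float]
) -> TestResult:
    """Two-sided rank-sum test.

    Enumerates the exact permutation null when the combined sample size is
    at most :data:`EXACT_RANKSUM_MAX_N` and there are no ties; otherwise
    uses the normal approximation with midranks, tie-corrected variance
    and continuity correction.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) == 0 or len(ya) == 0:
        raise DomainError("both samples must be non-empty")
    combined = np.concatenate([xa, ya])
    no_ties = len(np.unique(combined)) == len(combined)
    if len(combined) <= EXACT_RANKSUM_MAX_N and no_ties:
        res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method="exact")
        method = "wilcoxon_rank_sum_exact"
    else:
        res = sps.mannwhitneyu(
            xa, ya, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        method = "wilcoxon_rank_sum_normal_approx"
    return TestResult(
        p_value=min(float(res.pvalue), 1.0),
        statistic=float(res.statistic),
        method=method,
    )
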