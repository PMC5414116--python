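"""Group-level hypermutability statistics.

Per-locus mutant-cell frequencies from single-cell targeted sequencing are
compared between two groups with Fisher's exact test (per locus and
pooled); per-sample nonsynonymous mutation burdens are compared between
TET2-mutated and wild-type cohorts with the Wilcoxon rank-sum test; and
malignancy-lineage counts are summarised as percentages.

Per-locus testing applies no multiple-testing correction by default;
Bonferroni and Benjamini–Hochberg are available via ``correction``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .stats import (
    ContingencyTable2x2,
    DomainError,
    TestResult,
    fisher_exact_two_sided,
    wilcoxon_rank_sum_two_sided,
)

__all__ = [
    "LocusCellCounts",
    "CohortSample",
    "PanelResult",
    "BurdenResult",
    "per_locus_fisher",
    "burden_compare",
    "lineage_proportions",
]


@dataclass(frozen=True)
class LocusCellCounts:
    """Mutant/total cell counts for one locus in two groups."""

    locus_id: str
    counts: Dict[str, Tuple[int, int]]  # group -> (n_mutant, n_total)

    def __post_init__(self) -> None:
        if len(self.counts) != 2:
            raise DomainError(f"locus {self.locus_id}: exactly two groups required")
        for grp, (m, t) in self.counts.items():
            if not 0 <= m <= t:
                raise DomainError(
                    f"locus {self.locus_id}, group {grp}: need 0 <= mutant <= total"
                )


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    tet2_status: str  # "mutated" | "wild_type"
    n_mutations: int

    def __post_init__(self) -> None:
        if self.tet2_status not in ("mutated", "wild_type"):
            raise DomainError(f"unknown tet2_status {self.tet2_status!r}")
        if self.n_mutations < 0:
            raise DomainError("n_mutations must be >= 0")


@dataclass(frozen=True)
class PanelResult:
    per_locus: Dict[str, TestResult]
    n_significant: int
    alpha: float
    pooled: TestResult
    min_p: float


@dataclass(frozen=True)
class BurdenResult:
    test: TestResult
    medians: Dict[str, float]
    iqr: Dict[str, Tuple[float, float]]  # (25th, 75th percentile)
    n: Dict[str, int]


def per_locus_fisher(
    loci: Sequence[LocusCellCounts],
    alpha: float = 0.05,
    correction: Optional[str] = None,
) -> PanelResult:
    """Two-sided Fisher per locus plus a pooled test on summed counts.

    ``correction`` may be None (raw p-values), "bonferroni" or "bh"
    (Benjamini–Hochberg); significance is judged on the adjusted values.
    """
    if correction not in (None, "bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    raw: Dict[str, float] = {}
    pooled_counts: Dict[str, List[int]] = {}
    for locus in loci:
        groups = sorted(locus.counts)
        (m1, t1), (m2, t2) = (locus.counts[g] for g in groups)
        if t1 == 0 or t2 == 0:
            warnings.warn(
                f"locus {locus.locus_id}: zero total cells in a group, skipped",
                stacklevel=2,
            )
            continue
        table = ContingencyTable2x2(m1, t1 - m1, m2, t2 - m2)
        raw[locus.locus_id] = fisher_exact_two_sided(table).p_value
        for g, (m, t) in zip(groups, (locus.counts[g] for g in groups)):
            acc = pooled_counts.setdefault(g, [0, 0])
            acc[0] += m
            acc[1] += t
    if not raw:
        raise DomainError("no testable loci")
    adjusted = _adjust(list(raw.values()), correction)
    per_locus = {
        lid: TestResult(p_value=p_adj, method="fisher_exact_two_sided")
        for (lid, _), p_adj in zip(raw.items(), adjusted)
    }
    n_significant = sum(1 for r in per_locus.values() if r.p_value < alpha)
    g1, g2 = sorted(pooled_counts)
    (m1, t1), (m2, t2) = pooled_counts[g1], pooled_counts[g2]
    pooled = fisher_exact_two_sided(
        ContingencyTable2x2(m1, t1 - m1, m2, t2 - m2)
    )
    return PanelResult(
        per_locus=per_locus,
        n_significant=n_significant,
        alpha=alpha,
        pooled=pooled,
        min_p=min(r.p_value for r in per_locus.values()),
    )


def _adjust(pvals: List[float], correction: Optional[str]) -> List[float]:
    if correction is None:
        return pvals
    m = len(pvals)
    if correction == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    # Benjamini–Hochberg step-up
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        k = m - rank_from_top
        running = min(running, pvals[i] * m / k)
        adj[i] = running
    return list(adj)


def burden_compare(cohort: Sequence[CohortSample]) -> BurdenResult:
    """Wilcoxon rank-sum on per-sample burdens of mutated vs wild-type
    samples, with medians and interquartile ranges per group."""
    groups: Dict[str, List[int]] = {"mutated": [], "wild_type": []}
    for s in cohort:
        groups[s.tet2_status].append(s.n_mutations)
    if not groups["mutated"] or not groups["wild_type"]:
        raise DomainError("both TET2 groups must be non-empty")
    test = wilcoxon_rank_sum_two_sided(groups["mutated"], groups["wild_type"])
    medians = {g: float(np.median(v)) for g, v in groups.items()}
    iqr = {
        g: (float(np.percentile(v, 25)), float(np.percentile(v, 75)))
        for g, v in groups.items()
    }
    n = {g: len(v) for g, v in groups.items()}
    return BurdenResult(test=test, medians=medians, iqr=iqr, n=n)


def lineage_proportions(counts: Dict[str, int]) -> Dict[str, float]:
    """Percentages of each lineage label, half-up rounded to one decimal
    (whole percent when >= 10%)."""
    if any(c < 0 for c in counts.values()):
        raise DomainError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise DomainError("total count must be > 0")
    out: Dict[str, float] = {}
    for label, c in counts.items():
        pct = Decimal(100 * c) / Decimal(total)
        places = Decimal("1") if pct >= 10 else Decimal("0.1")
        out[label] = float(pct.quantize(places, rounding=ROUND_HALF_UP))
    return out
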