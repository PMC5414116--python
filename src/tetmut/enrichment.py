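"""Variant-to-category assignment and enrichment statistics.

Somatic variants are assigned to the three 5hmC/5mC dynamics categories by
their single changed base (SNVs) or first changed base (indels), and the
per-category counts are compared with a χ² goodness-of-fit whose expected
counts are proportional to each category's base-pair footprint — the null
in which mutations fall uniformly per base.  Also computes TET2-binding
coverage per category, the overlap between in-locus mutations and
TET2-binding peaks, and fold enrichment of a peak set over a genomic
feature relative to the feature's genomic coverage.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import IntervalSet, Variant, VariantKind, intersect
from .dhmr import CategorizedLoci, DhmrCategory
from .stats import DomainError, TestResult, chisq_goodness_of_fit, chisq_independence

__all__ = [
    "CategoryCounts",
    "EnrichmentResult",
    "BindingEnrichment",
    "assign_variants",
    "enrichment_test",
    "filter_c_to_t",
    "binding_enrichment",
    "binding_mutation_overlap",
    "feature_fold_enrichment",
]


@dataclass(frozen=True)
class CategoryCounts:
    n_variants: Dict[DhmrCategory, int]
    footprint_bp: Dict[DhmrCategory, int]
    unassigned_variants: int = 0

    @property
    def total_variants(self) -> int:
        return sum(self.n_variants.values()) + self.unassigned_variants

    @property
    def rates_per_mb(self) -> Dict[DhmrCategory, float]:
        """Variants per megabase of category footprint."""
        return {
            cat: (self.n_variants[cat] / (bp / 1e6) if bp else float("nan"))
            for cat, bp in self.footprint_bp.items()
        }


@dataclass(frozen=True)
class EnrichmentResult:
    counts: CategoryCounts
    test: TestResult


@dataclass(frozen=True)
class BindingEnrichment:
    """Per-category (covered_bp, uncovered_bp) by TET2 peaks, plus χ² test."""

    coverage: Dict[DhmrCategory, Tuple[int, int]]
    test: TestResult
    unit: str = "base"


def assign_variants(
    variants: Sequence[Variant], loci: CategorizedLoci
) -> CategoryCounts:
    """Count variants per category by their assigned base; the remainder
    is reported as unassigned background."""
    counts = {cat: 0 for cat in loci.loci}
    unassigned = 0
    by_chrom: Dict[str, List[int]] = {}
    order: Dict[str, List[int]] = {}
    for i, v in enumerate(variants):
        by_chrom.setdefault(v.chrom, []).append(v.assigned_base)
        order.setdefault(v.chrom, []).append(i)
    for chrom, positions in by_chrom.items():
        pos = np.asarray(positions, dtype=np.int64)
        hit = np.zeros(len(pos), dtype=bool)
        for cat, s in loci.loci.items():
            inside = s.contains_many(chrom, pos)
            counts[cat] += int(inside.sum())
            hit |= inside
        unassigned += int((~hit).sum())
    return CategoryCounts(
        n_variants=counts,
        footprint_bp=loci.footprint_bp,
        unassigned_variants=unassigned,
    )


def enrichment_test(counts: CategoryCounts) -> EnrichmentResult:
    """χ² goodness-of-fit of per-category counts against footprint-
    proportional expecteds; unassigned variants are excluded."""
    cats = [c for c, bp in counts.footprint_bp.items() if bp > 0]
    if len(cats) < 2:
        raise DomainError("need >= 2 categories with non-zero footprint")
    observed = [counts.n_variants[c] for c in cats]
    expected = [counts.footprint_bp[c] for c in cats]
    if sum(observed) == 0:
        raise DomainError("no variants assigned to any category")
    test = chisq_goodness_of_fit(observed, expected)
    return EnrichmentResult(counts=counts, test=test)


def filter_c_to_t(variants: Sequence[Variant]) -> List[Variant]:
    """Keep only C→T / G→A SNVs (the pyrimidine-collapsed C>T class)."""
    return [
        v
        for v in variants
        if v.kind is VariantKind.SNV and (v.ref, v.alt) in {("C", "T"), ("G", "A")}
    ]


def binding_enrichment(
    tet2_peaks: IntervalSet, loci: CategorizedLoci, unit: str = "base"
) -> BindingEnrichment:
    """TET2-binding coverage per category with a χ² test of independence.

    ``unit='base'`` counts covered vs uncovered bases of each category's
    footprint; ``unit='peak'`` counts category intervals with >=1 bp of
    TET2 overlap vs without.
    """
    if unit not in ("base", "peak"):
        raise ValueError("unit must be 'base' or 'peak'")
    if all(s.total_bp == 0 for s in loci.loci.values()):
        raise DomainError("empty categorized loci")
    tet2 = tet2_peaks.merge()
    coverage: Dict[DhmrCategory, Tuple[int, int]] = {}
    for cat, s in loci.loci.items():
        if unit == "base":
            covered = intersect(s, tet2).total_bp
            coverage[cat] = (covered, s.total_bp - covered)
        else:
            n_cov = sum(
                1
                for iv in s.intervals()
                if intersect(IntervalSet([iv]), tet2).total_bp > 0
            )
            coverage[cat] = (n_cov, len(s) - n_cov)
    table = [list(coverage[cat]) for cat in loci.loci if sum(coverage[cat]) > 0]
    test = chisq_independence(table)
    return BindingEnrichment(coverage=coverage, test=test, unit=unit)


def binding_mutation_overlap(
    variants_in_loci: Sequence[Variant], tet2_peaks: IntervalSet
) -> Tuple[int, int]:
    """(variants whose assigned base lies inside a TET2 peak, total)."""
    tet2 = tet2_peaks.merge()
    n_overlap = sum(
        1 for v in variants_in_loci if tet2.contains(v.chrom, v.assigned_base)
    )
    return n_overlap, len(variants_in_loci)


def feature_fold_enrichment(
    peaks: IntervalSet, feature: IntervalSet, genome_bp: int
) -> float:
    """Observed fraction of peaks overlapping a feature, over the fraction
    expected by chance from the feature's genomic coverage."""
    feature = feature.merge()
    feature_bp = feature.total_bp
    if feature_bp == 0:
        raise DomainError("feature has zero footprint")
    if genome_bp < feature_bp:
        raise DomainError("genome_bp smaller than feature footprint")
    peaks = peaks.merge()
    n_peaks = len(peaks)
    if n_peaks == 0:
        raise DomainError("no peaks supplied")
    n_overlap = sum(
        1
        for iv in peaks.intervals()
        if intersect(IntervalSet([iv]), feature).total_bp > 0
    )
    observed = n_overlap / n_peaks
    expected = feature_bp / genome_bp
    return observed / expected
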