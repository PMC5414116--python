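"""Mutation-spectrum summaries and CpG-proximity statistics.

Substitutions are collapsed to the six pyrimidine-centred classes (a G>A
on one strand is the same event as C>T on the other), indels are split
into +1 insertions, −1 deletions and everything longer, and each
variant's distance to the nearest CpG dinucleotide is compared against a
null model of CpG placement along the genome.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .core import ReferenceGenome, Variant, VariantKind
from .stats import DomainError

__all__ = [
    "SubstitutionClass",
    "SpectrumSummary",
    "CpGProximityResult",
    "CpGNullModel",
    "classify_substitution",
    "summarize_spectrum",
    "cpg_proximity",
    "expected_cpg_fraction",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SubstitutionClass(str, enum.Enum):
    """Pyrimidine-collapsed substitution classes."""

    C_TO_A = "C>A"
    C_TO_G = "C>G"
    C_TO_T = "C>T"
    T_TO_A = "T>A"
    T_TO_C = "T>C"
    T_TO_G = "T>G"

    @property
    def is_transition(self) -> bool:
        return self in (SubstitutionClass.C_TO_T, SubstitutionClass.T_TO_C)


def classify_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Collapse a single-base substitution to its pyrimidine-centred class
    (purine-reference pairs are reverse-complemented, e.g. G>A → C>T)."""
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise DomainError(f"invalid bases {ref!r}>{alt!r}")
    if ref == alt:
        raise DomainError("ref and alt must differ")
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return SubstitutionClass(f"{ref}>{alt}")


@dataclass(frozen=True)
class SpectrumSummary:
    """Counts and proportions of substitution classes and short indels."""

    class_counts: Dict[SubstitutionClass, int]
    n_plus1_insertions: int
    n_minus1_deletions: int
    n_other_indels: int

    @property
    def n_transitions(self) -> int:
        return sum(n for c, n in self.class_counts.items() if c.is_transition)

    @property
    def n_transversions(self) -> int:
        return sum(n for c, n in self.class_counts.items() if not c.is_transition)

    @property
    def n_total(self) -> int:
        return (
            self.n_transitions
            + self.n_transversions
            + self.n_plus1_insertions
            + self.n_minus1_deletions
            + self.n_other_indels
        )

    @property
    def proportions(self) -> Dict[str, float]:
        total = self.n_total
        return {
            "transitions": self.n_transitions / total,
            "transversions": self.n_transversions / total,
            "plus1_insertions": self.n_plus1_insertions / total,
            "minus1_deletions": self.n_minus1_deletions / total,
            "other_indels": self.n_other_indels / total,
        }

    @property
    def class_proportions(self) -> Dict[SubstitutionClass, float]:
        total = self.n_total
        return {c: n / total for c, n in self.class_counts.items()}


def summarize_spectrum(variants: Sequence[Variant]) -> SpectrumSummary:
    """Summarise SNVs by pyrimidine-collapsed class and indels by size."""
    if not variants:
        raise DomainError("empty variant list")
    class_counts = {c: 0 for c in SubstitutionClass}
    plus1 = minus1 = other = 0
    for v in variants:
        if v.kind is VariantKind.SNV:
            class_counts[classify_substitution(v.ref, v.alt)] += 1
        elif v.kind is VariantKind.INSERTION and v.indel_size == 1:
            plus1 += 1
        elif v.kind is VariantKind.DELETION and v.indel_size == -1:
            minus1 += 1
        else:
            other += 1
    return SpectrumSummary(
        class_counts=class_counts,
        n_plus1_insertions=plus1,
        n_minus1_deletions=minus1,
        n_other_indels=other,
    )


@dataclass(frozen=True)
class CpGProximityResult:
    window_bp: int
    n_total: int
    n_proximal: int

    @property
    def fraction(self) -> float:
        return self.n_proximal / self.n_total if self.n_total else float("nan")


def cpg_proximity(
    variants: Sequence[Variant], genome: ReferenceGenome, window_bp: int = 30
) -> CpGProximityResult:
    """Fraction of variants whose assigned base lies within ``window_bp``
    of either base of a CpG dinucleotide (inclusive distance)."""
    if window_bp < 0:
        raise DomainError("window_bp must be >= 0")
    cpg = genome.cpg_positions
    n_proximal = 0
    for v in variants:
        sites = cpg.get(v.chrom)
        if sites is None or not len(sites):
            continue
        p = v.assigned_base
        # proximal iff some CpG C-position c satisfies c in [p-w-1, p+w]
        # (distance to the C at c or the G at c+1 is <= w)
        lo = int(np.searchsorted(sites, p - window_bp - 1, side="left"))
        if lo < len(sites) and sites[lo] <= p + window_bp:
            n_proximal += 1
    return CpGProximityResult(
        window_bp=window_bp, n_total=len(variants), n_proximal=n_proximal
    )


@dataclass(frozen=True)
class CpGNullModel:
    """Null model for the expected near-CpG mutation fraction.

    ``exponential_gap`` treats CpG starts as a Poisson process with the
    given mean spacing; ``fixed_spacing`` assumes perfectly regular
    spacing; ``empirical_shuffle`` drops uniform random positions on a
    supplied genome and measures proximity directly.
    """

    mean_spacing_bp: float = 100.0
    window_bp: int = 30
    model: str = "exponential_gap"

    def __post_init__(self) -> None:
        if self.mean_spacing_bp <= 0:
            raise DomainError("mean_spacing_bp must be > 0")
        if self.window_bp < 0:
            raise DomainError("window_bp must be >= 0")
        if self.model not in ("exponential_gap", "fixed_spacing", "empirical_shuffle"):
            raise DomainError(f"unknown null model {self.model!r}")


def expected_cpg_fraction(
    null: CpGNullModel,
    genome: Optional[ReferenceGenome] = None,
    n_positions: int = 100_000,
    seed: int = 0,
) -> float:
    """Expected fraction of uniformly placed mutations within the window.

    Under ``exponential_gap`` a window of ±w around a 2-bp CpG captures a
    position iff a CpG start falls within 2w+2 bp of it, giving the closed
    form 1 − exp(−(2w+2)/λ) for mean spacing λ.  ``fixed_spacing`` returns
    min(1, (2w+2)/λ).  ``empirical_shuffle`` requires ``genome``.
    """
    w, lam = null.window_bp, null.mean_spacing_bp
    if null.model == "exponential_gap":
        return 1.0 - math.exp(-(2 * w + 2) / lam)
    if null.model == "fixed_spacing":
        return min(1.0, (2 * w + 2) / lam)
    if genome is None:
        raise DomainError("empirical_shuffle requires a genome")
    rng = np.random.default_rng(seed)
    chroms = genome.chroms
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    choices = rng.choice(len(chroms), size=n_positions, p=lengths / lengths.sum())
    n_prox = 0
    for ci in range(len(chroms)):
        n = int((choices == ci).sum())
        if n == 0:
            continue
        sites = genome.cpg_positions[chroms[ci]]
        pos = rng.integers(0, int(lengths[ci]), size=n)
        if not len(sites):
            continue
        lo = np.searchsorted(sites, pos - w - 1, side="left")
        ok = lo < len(sites)
        hits = np.zeros(n, dtype=bool)
        hits[ok] = sites[np.minimum(lo[ok], len(sites) - 1)] <= pos[ok] + w
        n_prox += int(hits.sum())
    return n_prox / n_positions
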