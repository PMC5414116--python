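"""Three-way classification of loci by 5hmC/5mC peak dynamics.

Comparing peak sets between a wild-type (WT) and a TET2-knockout (KO)
condition, every classified base falls in exactly one of three categories:

* ``HMC_GAIN`` — a 5hmC peak present in KO but absent in WT.  These are
  sites where TET2 normally performs the further oxidation of 5hmC, so the
  mark accumulates once TET2 is lost.
* ``HMC_LOSS_OR_MC_GAIN`` — a 5hmC peak lost in KO, or a 5mC peak gained
  in KO: sites whose first oxidation step (5mC→5hmC) depends on TET2.
* ``NO_CHANGE`` — 5hmC peaks shared by both conditions.

Peak gain/loss is judged at the whole-peak level: a peak counts as
condition-specific when the fraction of its bases covered by the other
condition's peak set does not exceed ``min_overlap_fraction`` (default 0,
i.e. any overlap disqualifies).  The resulting whole-peak footprints are
then made base-level disjoint with precedence
GAIN > LOSS_OR_MC_GAIN > NO_CHANGE.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, List, Tuple

from .core import GenomicInterval, IntervalSet, intersect, subtract

__all__ = [
    "Mark",
    "Condition",
    "MarkPeaks",
    "DhmrCategory",
    "CategorizedLoci",
    "diff_peaks",
    "classify_loci",
]


class Mark(str, enum.Enum):
    HMC = "5hmC"
    MC = "5mC"


class Condition(str, enum.Enum):
    WT = "WT"
    KO = "KO"


@dataclass(frozen=True)
class MarkPeaks:
    condition: Condition
    mark: Mark
    peaks: IntervalSet

    def normalized(self) -> "MarkPeaks":
        return MarkPeaks(self.condition, self.mark, self.peaks.merge())


class DhmrCategory(str, enum.Enum):
    NO_CHANGE = "no_change"
    HMC_LOSS_OR_MC_GAIN = "hmc_loss_or_mc_gain"
    HMC_GAIN = "hmc_gain"


@dataclass(frozen=True)
class CategorizedLoci:
    """Base-level disjoint footprints for the three categories."""

    loci: Dict[DhmrCategory, IntervalSet]

    @property
    def footprint_bp(self) -> Dict[DhmrCategory, int]:
        return {cat: s.total_bp for cat, s in self.loci.items()}

    def __getitem__(self, cat: DhmrCategory) -> IntervalSet:
        return self.loci[cat]

    def category_of(self, chrom: str, pos: int) -> "DhmrCategory | None":
        for cat, s in self.loci.items():
            if s.contains(chrom, pos):
                return cat
        return None


def diff_peaks(
    reference: IntervalSet,
    query: IntervalSet,
    min_overlap_fraction: float = 0.0,
) -> Tuple[IntervalSet, IntervalSet, IntervalSet]:
    """Split peaks into (gained, lost, shared) relative to ``reference``.

    A query peak is *gained* when the fraction of its bases covered by the
    reference footprint is at most ``min_overlap_fraction`` (0 means any
    overlap disqualifies); symmetrically a reference peak is *lost* when
    barely covered by the query.  ``shared`` is the exact base-level
    intersection.
    """
    if not 0.0 <= min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must lie in [0, 1]")
    reference = reference.merge()
    query = query.merge()
    gained = _absent_peaks(query, reference, min_overlap_fraction)
    lost = _absent_peaks(reference, query, min_overlap_fraction)
    shared = intersect(reference, query)
    return gained, lost, shared


def _absent_peaks(
    peaks: IntervalSet, other: IntervalSet, max_frac: float
) -> IntervalSet:
    kept: List[GenomicInterval] = []
    for iv in peaks.intervals():
        one = IntervalSet([iv])
        overlap = intersect(one, other).total_bp
        if overlap <= max_frac * iv.length:
            kept.append(iv)
    return IntervalSet(kept)


def classify_loci(
    hmc_wt: MarkPeaks,
    hmc_ko: MarkPeaks,
    mc_wt: MarkPeaks,
    mc_ko: MarkPeaks,
    min_overlap_fraction: float = 0.0,
) -> CategorizedLoci:
    """Partition the genome's peak footprints into the three categories."""
    _check(hmc_wt, Mark.HMC, Condition.WT)
    _check(hmc_ko, Mark.HMC, Condition.KO)
    _check(mc_wt, Mark.MC, Condition.WT)
    _check(mc_ko, Mark.MC, Condition.KO)

    hmc_gained, hmc_lost, hmc_shared = diff_peaks(
        hmc_wt.peaks, hmc_ko.peaks, min_overlap_fraction
    )
    mc_gained, _, _ = diff_peaks(mc_wt.peaks, mc_ko.peaks, min_overlap_fraction)

    gain = hmc_gained.merge()
    loss_raw = IntervalSet(
        list(hmc_lost.intervals()) + list(mc_gained.intervals())
    ).merge()
    loss = subtract(loss_raw, gain)
    no_change = subtract(subtract(hmc_shared.merge(), gain), loss)
    return CategorizedLoci(
        {
            DhmrCategory.HMC_GAIN: gain,
            DhmrCategory.HMC_LOSS_OR_MC_GAIN: loss,
            DhmrCategory.NO_CHANGE: no_change,
        }
    )


def _check(p: MarkPeaks, mark: Mark, condition: Condition) -> None:
    if p.mark is not mark or p.condition is not condition:
        raise ValueError(
            f"expected {mark.value}/{condition.value} peaks, got "
            f"{p.mark.value}/{p.condition.value}"
        )
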