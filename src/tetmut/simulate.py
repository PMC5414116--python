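"""Truth-labelled synthetic data for every pipeline stage.

Generates toy genomes with CpG dinucleotides at a configurable mean
spacing, WT/KO peak sets realizing the three 5hmC/5mC dynamics
categories, somatic variants with configurable per-category rates,
substitution-spectrum weights and CpG-proximity bias, TET2-binding peaks,
two-group mutation-burden cohorts, single-cell locus panels and Poisson
fluctuation-assay colony counts.  Every generator is deterministic under
a fixed root seed: per-stage random streams are spawned from the root via
``numpy.random.SeedSequence`` spawn keys, so each stage can be
regenerated independently.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cohort import CohortSample, LocusCellCounts
from .core import GenomicInterval, IntervalSet, ReferenceGenome, Variant, subtract
from .dhmr import Condition, DhmrCategory, Mark, MarkPeaks
from .fluctuation import FluctuationAssayInput

__all__ = [
    "ConfigurationError",
    "GenomeConfig",
    "PeakConfig",
    "TetBindingConfig",
    "MutationConfig",
    "CohortConfig",
    "PanelConfig",
    "AssayConfig",
    "SimulationConfig",
    "PeakTruth",
    "VariantTruth",
    "SimulatedStudy",
    "simulate_genome",
    "simulate_peaks",
    "simulate_tet2_binding",
    "simulate_mutations",
    "simulate_cohort",
    "simulate_locus_panel",
    "simulate_fluctuation",
    "simulate_study",
]

_STAGE = {
    "genome": 0,
    "peaks": 1,
    "mutations": 2,
    "cohort": 3,
    "assay": 4,
    "tet2": 5,
    "panel": 6,
}

_BACKGROUND = "background"

# default substitution/indel weights: 35% C:G>T:A and 23% T:A>C:G
# transitions, 38% transversions (split evenly), 4% ±1 indels with −1
# deletions more common than +1 insertions
_DEFAULT_SPECTRUM = {
    "C>T": 0.35,
    "T>C": 0.23,
    "C>A": 0.095,
    "C>G": 0.095,
    "T>A": 0.095,
    "T>G": 0.095,
    "plus1_insertion": 0.015,
    "minus1_deletion": 0.025,
}


class ConfigurationError(ValueError):
    """Simulation parameters are inconsistent or infeasible."""


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGE[stage],))
    )


@dataclass(frozen=True)
class GenomeConfig:
    n_chroms: int = 2
    chrom_length_bp: int = 200_000
    gc_fraction: float = 0.42
    cpg_mean_spacing_bp: float = 100.0


@dataclass(frozen=True)
class PeakConfig:
    n_peaks_per_category: int = 30
    peak_length_mean_bp: int = 1_000
    min_gap_bp: int = 200


@dataclass(frozen=True)
class TetBindingConfig:
    frac_gain_covered: float = 0.7
    n_background_peaks: int = 0
    peak_length_mean_bp: int = 800


@dataclass(frozen=True)
class MutationConfig:
    n_total: int = 600
    rate_multipliers: Dict[str, float] = field(
        default_factory=lambda: {
            DhmrCategory.NO_CHANGE.value: 1.0,
            DhmrCategory.HMC_LOSS_OR_MC_GAIN.value: 1.0,
            DhmrCategory.HMC_GAIN.value: 3.0,
            _BACKGROUND: 1.0,
        }
    )
    spectrum_weights: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SPECTRUM)
    )
    # with the exponential-gap null at ~46% for spacing 100 / window 30,
    # a bias of 0.5 puts ~73% of mutations at or near CpG sites overall
    cpg_proximity_bias: float = 0.5
    cpg_window_bp: int = 30


@dataclass(frozen=True)
class CohortConfig:
    n_mutated: int = 41
    n_wild_type: int = 154
    mean_wild_type: float = 10.0
    mean_ratio: float = 1.5
    dispersion: float = 5.0


@dataclass(frozen=True)
class PanelConfig:
    n_loci: int = 13
    n_elevated: int = 7
    cells_per_group: int = 50
    baseline_fraction: float = 0.02
    # Large separation so that, at 50 cells per group, every truly
    # elevated locus is individually detected with near-certain power.
    elevated_fraction: float = 0.40


@dataclass(frozen=True)
class AssayConfig:
    true_frequency: float = 1e-5
    plating_efficiency: float = 0.5
    cells_per_dish: int = 500_000
    n_dishes: int = 3
    cells_plated_pe: int = 500


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    tet2: TetBindingConfig = field(default_factory=TetBindingConfig)
    mutations: MutationConfig = field(default_factory=MutationConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    assay: AssayConfig = field(default_factory=AssayConfig)

    @classmethod
    def from_dict(cls, data: Dict) -> "SimulationConfig":
        sections = {
            "genome": GenomeConfig,
            "peaks": PeakConfig,
            "tet2": TetBindingConfig,
            "mutations": MutationConfig,
            "cohort": CohortConfig,
            "panel": PanelConfig,
            "assay": AssayConfig,
        }
        kwargs: Dict = {}
        for key, value in data.items():
            if key == "seed":
                kwargs["seed"] = int(value)
            elif key in sections:
                typ = sections[key]
                names = {f.name for f in dataclasses.fields(typ)}
                unknown = set(value) - names
                if unknown:
                    raise ConfigurationError(
                        f"unknown key(s) {sorted(unknown)} in section {key!r}"
                    )
                kwargs[key] = typ(**value)
            else:
                raise ConfigurationError(f"unknown config section {key!r}")
        return cls(**kwargs)


@dataclass(frozen=True)
class PeakTruth:
    """Intended category (and 5hmC-loss vs 5mC-gain subtype) of a region."""

    interval: GenomicInterval
    category: DhmrCategory
    subtype: Optional[str] = None  # for HMC_LOSS_OR_MC_GAIN


@dataclass(frozen=True)
class VariantTruth:
    chrom: str
    pos: int  # 1-based, matches the emitted variant
    category: str  # DhmrCategory value or "background"
    class_label: str
    near_cpg: bool


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: ReferenceGenome
    mark_peaks: Dict[Tuple[str, str], MarkPeaks]  # (mark, condition) -> peaks
    peak_truth: List[PeakTruth]
    tet2_peaks: IntervalSet
    variants: List[Variant]
    variant_truth: List[VariantTruth]
    cohort: List[CohortSample]
    panel: List[LocusCellCounts]
    panel_elevated: List[str]
    assay_control: FluctuationAssayInput
    assay_test: FluctuationAssayInput


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> ReferenceGenome:
    """Random genome with CpG starts spaced by 2 + Exp(λ−2) gaps.

    The start-to-start spacing then has the configured mean λ; λ=2 is the
    degenerate tandem-CG case.  Accidental CG dinucleotides arising from
    the random background are broken (the G is flipped to A) so the CpG
    positions are exactly the planted ones and the realized mean spacing
    matches the configuration.
    """
    g = config.genome
    lam = g.cpg_mean_spacing_bp
    if lam < 2:
        raise ConfigurationError("cpg_mean_spacing_bp must be >= 2")
    rng = _stage_rng(config.seed, "genome")
    gc = g.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences: Dict[str, str] = {}
    for ci in range(g.n_chroms):
        n = g.chrom_length_bp
        seq = alphabet[rng.choice(4, size=n, p=probs)].copy()
        # plant CpGs
        planted = []
        pos = int(rng.exponential(max(lam - 2, 0.0))) if lam > 2 else 0
        while pos + 1 < n:
            planted.append(pos)
            gap = 2 + (rng.exponential(lam - 2) if lam > 2 else 0.0)
            pos += max(2, int(round(gap)))
        planted_arr = np.array(planted, dtype=np.int64)
        seq[planted_arr] = ord("C")
        seq[planted_arr + 1] = ord("G")
        # break accidental CGs outside the planted set
        planted_set = set(planted)
        cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
        for p in cg:
            if int(p) not in planted_set:
                seq[p + 1] = ord("A")
        sequences[f"chr{ci + 1}"] = seq.tobytes().decode("ascii")
    return ReferenceGenome(sequences)


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


def simulate_peaks(
    config: SimulationConfig, genome: ReferenceGenome
) -> Tuple[Dict[Tuple[str, str], MarkPeaks], List[PeakTruth]]:
    """Place non-adjacent peaks realizing the three categories.

    NO_CHANGE regions carry a 5hmC peak in both conditions; HMC_GAIN
    regions a 5hmC peak in KO only; HMC_LOSS_OR_MC_GAIN regions alternate
    between a 5hmC peak in WT only (loss) and a 5mC peak in KO only
    (gain).  Gaps of at least ``min_gap_bp`` keep the truth unambiguous.
    """
    p = config.peaks
    rng = _stage_rng(config.seed, "peaks")
    n_cat = p.n_peaks_per_category
    categories = (
        [DhmrCategory.NO_CHANGE] * n_cat
        + [DhmrCategory.HMC_LOSS_OR_MC_GAIN] * n_cat
        + [DhmrCategory.HMC_GAIN] * n_cat
    )
    rng.shuffle(categories)  # type: ignore[arg-type]
    loss_subtypes = ["hmc_loss", "mc_gain"] * (n_cat // 2 + 1)

    truth: List[PeakTruth] = []
    idx = 0
    n_loss_seen = 0
    for chrom in genome.chroms:
        length = genome.length(chrom)
        cursor = p.min_gap_bp
        while idx < len(categories):
            peak_len = max(50, int(round(rng.normal(p.peak_length_mean_bp,
                                                    0.15 * p.peak_length_mean_bp))))
            gap = p.min_gap_bp + int(rng.integers(0, p.min_gap_bp + 1))
            if cursor + peak_len + p.min_gap_bp > length:
                break
            cat = categories[idx]
            subtype = None
            if cat is DhmrCategory.HMC_LOSS_OR_MC_GAIN:
                subtype = loss_subtypes[n_loss_seen]
                n_loss_seen += 1
            truth.append(
                PeakTruth(GenomicInterval(chrom, cursor, cursor + peak_len),
                          cat, subtype)
            )
            cursor += peak_len + gap
            idx += 1
        if idx >= len(categories):
            break
    if idx < len(categories):
        raise ConfigurationError(
            f"cannot place {len(categories)} peaks with min_gap "
            f"{p.min_gap_bp} bp in a {genome.total_bp} bp genome"
        )

    hmc_wt, hmc_ko, mc_wt, mc_ko = [], [], [], []
    for t in truth:
        if t.category is DhmrCategory.NO_CHANGE:
            hmc_wt.append(t.interval)
            hmc_ko.append(t.interval)
        elif t.category is DhmrCategory.HMC_GAIN:
            hmc_ko.append(t.interval)
        elif t.subtype == "hmc_loss":
            hmc_wt.append(t.interval)
        else:  # mc_gain
            mc_ko.append(t.interval)
    mark_peaks = {
        (Mark.HMC.value, Condition.WT.value): MarkPeaks(
            Condition.WT, Mark.HMC, IntervalSet(hmc_wt)),
        (Mark.HMC.value, Condition.KO.value): MarkPeaks(
            Condition.KO, Mark.HMC, IntervalSet(hmc_ko)),
        (Mark.MC.value, Condition.WT.value): MarkPeaks(
            Condition.WT, Mark.MC, IntervalSet(mc_wt)),
        (Mark.MC.value, Condition.KO.value): MarkPeaks(
            Condition.KO, Mark.MC, IntervalSet(mc_ko)),
    }
    return mark_peaks, truth


def simulate_tet2_binding(
    config: SimulationConfig,
    genome: ReferenceGenome,
    peak_truth: Sequence[PeakTruth],
) -> IntervalSet:
    """TET2-binding peaks covering a configurable fraction of gained-5hmC
    regions, plus optional unrelated background peaks."""
    t = config.tet2
    rng = _stage_rng(config.seed, "tet2")
    ivals: List[GenomicInterval] = []
    for pt in peak_truth:
        if pt.category is DhmrCategory.HMC_GAIN and rng.random() < t.frac_gain_covered:
            pad = int(rng.integers(0, 50))
            iv = pt.interval
            ivals.append(
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.start - pad),
                    min(genome.length(iv.chrom), iv.end + pad),
                )
            )
    for _ in range(t.n_background_peaks):
        chrom = genome.chroms[int(rng.integers(0, len(genome.chroms)))]
        length = max(50, int(round(rng.normal(t.peak_length_mean_bp,
                                              0.15 * t.peak_length_mean_bp))))
        start = int(rng.integers(0, max(1, genome.length(chrom) - length)))
        ivals.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivals)


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------


class _FootprintSampler:
    """Uniform position sampler over an interval set's footprint."""

    def __init__(self, interval_set: IntervalSet) -> None:
        merged = interval_set.merge()
        self.chroms: List[str] = []
        self.starts: List[int] = []
        self.ends: List[int] = []
        for iv in merged.intervals():
            self.chroms.append(iv.chrom)
            self.starts.append(iv.start)
            self.ends.append(iv.end)
        lengths = np.array(
            [e - s for s, e in zip(self.starts, self.ends)], dtype=np.int64
        )
        self.cum = np.concatenate([[0], np.cumsum(lengths)])
        self.total = int(self.cum[-1])

    def sample(self, rng: np.random.Generator) -> Tuple[str, int]:
        off = int(rng.integers(0, self.total))
        i = int(np.searchsorted(self.cum, off, side="right")) - 1
        return self.chroms[i], self.starts[i] + (off - int(self.cum[i]))


def _category_sets(
    genome: ReferenceGenome, peak_truth: Sequence[PeakTruth]
) -> Dict[str, IntervalSet]:
    by_cat: Dict[str, List[GenomicInterval]] = {c.value: [] for c in DhmrCategory}
    for t in peak_truth:
        by_cat[t.category.value].append(t.interval)
    whole = IntervalSet(
        [GenomicInterval(c, 0, genome.length(c)) for c in genome.chroms]
    )
    all_peaks = IntervalSet([t.interval for t in peak_truth])
    sets = {cat: IntervalSet(ivs) for cat, ivs in by_cat.items()}
    sets[_BACKGROUND] = subtract(whole, all_peaks)
    return sets


def _near_cpg(genome: ReferenceGenome, chrom: str, pos0: int, window: int) -> bool:
    sites = genome.cpg_positions.get(chrom)
    if sites is None or not len(sites):
        return False
    lo = int(np.searchsorted(sites, pos0 - window - 1, side="left"))
    return bool(lo < len(sites) and sites[lo] <= pos0 + window)


_PYRIMIDINE_FOR = {"C>T": "C", "T>C": "T", "C>A": "C", "C>G": "C",
                   "T>A": "T", "T>G": "T"}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_mutations(
    config: SimulationConfig,
    genome: ReferenceGenome,
    peak_truth: Sequence[PeakTruth],
) -> Tuple[List[Variant], List[VariantTruth]]:
    """Place variants with per-bp rate ∝ category multiplier.

    Per-category counts are multinomial with probabilities proportional
    to footprint × multiplier.  Each variant's class is drawn from the
    spectrum weights and its position rejection-sampled within the
    category footprint until the reference base is compatible with the
    class (C/G for pyrimidine-C classes, T/A for pyrimidine-T classes).
    With probability ``cpg_proximity_bias`` the position is drawn from
    the part of the footprint within ±window of a CpG instead.
    """
    m = config.mutations
    rng = _stage_rng(config.seed, "mutations")
    weights = dict(m.spectrum_weights)
    total_w = sum(weights.values())
    if not np.isclose(total_w, 1.0, atol=1e-6):
        raise ConfigurationError("spectrum_weights must sum to 1")
    if m.cpg_proximity_bias < 0 or m.cpg_proximity_bias > 1:
        raise ConfigurationError("cpg_proximity_bias must lie in [0, 1]")

    sets = _category_sets(genome, peak_truth)
    strata = [s for s in sets if sets[s].total_bp > 0 and
              m.rate_multipliers.get(s, 0.0) > 0]
    probs = np.array(
        [sets[s].total_bp * m.rate_multipliers[s] for s in strata], dtype=float
    )
    if probs.sum() <= 0:
        raise ConfigurationError("no stratum has positive rate × footprint")
    counts = rng.multinomial(m.n_total, probs / probs.sum())

    cpg_ivals: List[GenomicInterval] = []
    if m.cpg_proximity_bias > 0:
        w = m.cpg_window_bp
        for chrom, sites in genome.cpg_positions.items():
            length = genome.length(chrom)
            for c in sites:
                cpg_ivals.append(
                    GenomicInterval(chrom, max(0, int(c) - w),
                                    min(length, int(c) + w + 2))
                )
    cpg_set = IntervalSet(cpg_ivals).merge() if cpg_ivals else None

    class_names = list(weights)
    class_probs = np.array([weights[c] for c in class_names])
    variants: List[Variant] = []
    truth: List[VariantTruth] = []
    for stratum, n in zip(strata, counts):
        if n == 0:
            continue
        plain = _FootprintSampler(sets[stratum])
        biased = None
        if cpg_set is not None:
            from .core import intersect  # local to avoid cycle at import time

            near = intersect(sets[stratum], cpg_set)
            if near.total_bp > 0:
                biased = _FootprintSampler(near)
        for _ in range(int(n)):
            label = class_names[int(rng.choice(len(class_names), p=class_probs))]
            sampler = (
                biased
                if biased is not None and rng.random() < m.cpg_proximity_bias
                else plain
            )
            variant = _place_variant(rng, genome, sampler, label)
            variants.append(variant)
            truth.append(
                VariantTruth(
                    chrom=variant.chrom,
                    pos=variant.pos,
                    category=stratum,
                    class_label=label,
                    near_cpg=_near_cpg(
                        genome, variant.chrom, variant.assigned_base,
                        m.cpg_window_bp,
                    ),
                )
            )
    return variants, truth


def _place_variant(
    rng: np.random.Generator,
    genome: ReferenceGenome,
    sampler: _FootprintSampler,
    label: str,
    max_tries: int = 2000,
) -> Variant:
    for _ in range(max_tries):
        chrom, p = sampler.sample(rng)
        seq = genome.sequences[chrom]
        if label in _PYRIMIDINE_FOR:
            ref = seq[p]
            if ref == "N":
                continue
            pyr, alt_pyr = label.split(">")
            if ref == pyr:
                return Variant(chrom, p + 1, ref, alt_pyr)
            if ref == _COMPLEMENT[pyr]:
                return Variant(chrom, p + 1, ref, _COMPLEMENT[alt_pyr])
            continue
        # ±1 indels anchor at p-1 so the first changed base is p
        if p < 1 or p + 1 >= len(seq):
            continue
        anchor, here = seq[p - 1], seq[p]
        if "N" in (anchor, here):
            continue
        if label == "minus1_deletion":
            return Variant(chrom, p, anchor + here, anchor)
        if label == "plus1_insertion":
            inserted = "ACGT"[int(rng.integers(0, 4))]
            return Variant(chrom, p, anchor, anchor + inserted)
        raise ConfigurationError(f"unknown spectrum class {label!r}")
    raise ConfigurationError(
        f"could not place a {label!r} variant after {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# Cohort, panel, assay
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> List[CohortSample]:
    """Negative-binomial mutation burdens for TET2-mutated vs wild-type
    samples (mutated-group mean = mean_wild_type × mean_ratio)."""
    c = config.cohort
    if c.mean_wild_type <= 0 or c.dispersion <= 0 or c.mean_ratio <= 0:
        raise ConfigurationError("cohort means, ratio and dispersion must be > 0")
    rng = _stage_rng(config.seed, "cohort")
    samples: List[CohortSample] = []

    def draw(mean: float, size: int) -> np.ndarray:
        p = c.dispersion / (c.dispersion + mean)
        return rng.negative_binomial(c.dispersion, p, size=size)

    for i, burden in enumerate(draw(c.mean_wild_type * c.mean_ratio, c.n_mutated)):
        samples.append(CohortSample(f"mut_{i + 1:03d}", "mutated", int(burden)))
    for i, burden in enumerate(draw(c.mean_wild_type, c.n_wild_type)):
        samples.append(CohortSample(f"wt_{i + 1:03d}", "wild_type", int(burden)))
    return samples


def simulate_locus_panel(
    config: SimulationConfig,
) -> Tuple[List[LocusCellCounts], List[str]]:
    """Single-cell mutant counts for a targeted locus panel.

    A configurable subset of loci has an elevated mutant-cell fraction in
    the knockout group; all other loci (and the wild-type group
    everywhere) sit at the baseline fraction.  Returns the panel and the
    ids of the truly elevated loci.
    """
    p = config.panel
    if not 0 <= p.n_elevated <= p.n_loci:
        raise ConfigurationError("n_elevated must lie in [0, n_loci]")
    rng = _stage_rng(config.seed, "panel")
    elevated_idx = set(
        rng.choice(p.n_loci, size=p.n_elevated, replace=False).tolist()
    )
    panel: List[LocusCellCounts] = []
    elevated_ids: List[str] = []
    for i in range(p.n_loci):
        locus_id = f"locus_{i + 1:02d}"
        frac_ko = p.elevated_fraction if i in elevated_idx else p.baseline_fraction
        if i in elevated_idx:
            elevated_ids.append(locus_id)
        n = p.cells_per_group
        panel.append(
            LocusCellCounts(
                locus_id,
                {
                    "ko": (int(rng.binomial(n, frac_ko)), n),
                    "wt": (int(rng.binomial(n, p.baseline_fraction)), n),
                },
            )
        )
    return panel, elevated_ids


def simulate_fluctuation(
    config: SimulationConfig, true_frequency: Optional[float] = None
) -> FluctuationAssayInput:
    """Poisson 6-TG colony counts and binomial plating-efficiency counts.

    Colonies under selection are Poisson(cells × frequency × PE): only
    mutant cells that also form colonies are scored.
    """
    a = config.assay
    f = a.true_frequency if true_frequency is None else true_frequency
    if not 0 <= f <= 1:
        raise ConfigurationError("true_frequency must lie in [0, 1]")
    rng = _stage_rng(config.seed, "assay")
    cells_total = a.cells_per_dish * a.n_dishes
    colonies_6tg = int(rng.poisson(cells_total * f * a.plating_efficiency))
    colonies_pe = int(rng.binomial(a.cells_plated_pe, a.plating_efficiency))
    return FluctuationAssayInput(
        cells_plated_selection=cells_total,
        colonies_6tg=colonies_6tg,
        cells_plated_pe=a.cells_plated_pe,
        colonies_pe=max(colonies_pe, 1),  # PE control virtually never zero
    )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator under one root seed."""
    genome = simulate_genome(config)
    mark_peaks, peak_truth = simulate_peaks(config, genome)
    tet2 = simulate_tet2_binding(config, genome, peak_truth)
    variants, variant_truth = simulate_mutations(config, genome, peak_truth)
    cohort = simulate_cohort(config)
    panel, elevated = simulate_locus_panel(config)
    control = simulate_fluctuation(config, true_frequency=config.assay.true_frequency)
    # knockdown condition: same protocol at a 24-fold higher frequency
    test_cfg = dataclasses.replace(config, seed=config.seed + 1)
    test = simulate_fluctuation(
        test_cfg, true_frequency=min(1.0, config.assay.true_frequency * 24)
    )
    return SimulatedStudy(
        config=config,
        genome=genome,
        mark_peaks=mark_peaks,
        peak_truth=peak_truth,
        tet2_peaks=tet2,
        variants=variants,
        variant_truth=variant_truth,
        cohort=cohort,
        panel=panel,
        panel_elevated=elevated,
        assay_control=control,
        assay_test=test,
    )
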