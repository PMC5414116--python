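import numpy as np
import pytest

from tetmut.core import GenomicInterval, IntervalSet, Variant
from tetmut.dhmr import CategorizedLoci, DhmrCategory
from tetmut.enrichment import (
    CategoryCounts,
    assign_variants,
    binding_enrichment,
    binding_mutation_overlap,
    enrichment_test,
    feature_fold_enrichment,
    filter_c_to_t,
)
from tetmut.stats import DomainError

from oracles import interval_set_mask


def loci_from(gain=(), loss=(), nochange=()):
    return CategorizedLoci(
        {
            DhmrCategory.HMC_GAIN: IntervalSet(gain),
            DhmrCategory.HMC_LOSS_OR_MC_GAIN: IntervalSet(loss),
            DhmrCategory.NO_CHANGE: IntervalSet(nochange),
        }
    )


GAIN = [GenomicInterval("chr1", 100, 200)]
LOSS = [GenomicInterval("chr1", 300, 400)]
NOCH = [GenomicInterval("chr1", 500, 600)]


# ------------------------------------------------------------- assignment


def test_assignment_by_base_and_unassigned():
    loci = loci_from(GAIN, LOSS, NOCH)
    variants = [
        Variant("chr1", 150, "A", "G"),   # inside GAIN
        Variant("chr1", 100, "A", "G"),   # 1-based 100 -> 0-based 99, outside
        Variant("chr1", 350, "AT", "A"),  # deletion, first changed base 350
        Variant("chr1", 700, "A", "G"),   # background
    ]
    counts = assign_variants(variants, loci)
    assert counts.n_variants[DhmrCategory.HMC_GAIN] == 1
    assert counts.n_variants[DhmrCategory.HMC_LOSS_OR_MC_GAIN] == 1
    assert counts.n_variants[DhmrCategory.NO_CHANGE] == 0
    assert counts.unassigned_variants == 2
    assert counts.total_variants == 4


def test_assignment_matches_simulated_truth(small_study):
    by_cat = {}
    for t in small_study.peak_truth:
        by_cat.setdefault(t.category, []).append(t.interval)
    loci = CategorizedLoci({c: IntervalSet(by_cat.get(c, [])) for c in DhmrCategory})
    counts = assign_variants(small_study.variants, loci)
    truth_counts = {c: 0 for c in DhmrCategory}
    unassigned = 0
    for t in small_study.variant_truth:
        if t.category == "background":
            unassigned += 1
        else:
            truth_counts[DhmrCategory(t.category)] += 1
    assert counts.n_variants == truth_counts
    assert counts.unassigned_variants == unassigned


# -------------------------------------------------------------- enrichment


def test_enrichment_flat_counts_flat_footprints():
    counts = CategoryCounts(
        n_variants={c: 20 for c in DhmrCategory},
        footprint_bp={c: 1_000_000 for c in DhmrCategory},
    )
    res = enrichment_test(counts)
    assert res.test.statistic == pytest.approx(0.0)
    assert res.test.p_value == pytest.approx(1.0)


def test_enrichment_closed_form():
    counts = CategoryCounts(
        n_variants=dict(zip(DhmrCategory, (10, 10, 40))),
        footprint_bp={c: 1_000_000 for c in DhmrCategory},
    )
    res = enrichment_test(counts)
    assert res.test.statistic == pytest.approx(30.0)
    assert res.test.df == 2


def test_enrichment_rates_and_category_order_invariance():
    counts = CategoryCounts(
        n_variants=dict(zip(DhmrCategory, (5, 10, 30))),
        footprint_bp=dict(zip(DhmrCategory, (500_000, 1_000_000, 1_000_000))),
    )
    rates = counts.rates_per_mb
    assert rates[DhmrCategory.NO_CHANGE] == pytest.approx(10.0)
    p1 = enrichment_test(counts).test.p_value
    reordered = CategoryCounts(
        n_variants={c: counts.n_variants[c] for c in reversed(list(DhmrCategory))},
        footprint_bp={c: counts.footprint_bp[c] for c in reversed(list(DhmrCategory))},
    )
    assert enrichment_test(reordered).test.p_value == pytest.approx(p1)


def test_enrichment_requires_footprints_and_variants():
    zero = CategoryCounts(
        n_variants={c: 0 for c in DhmrCategory},
        footprint_bp={c: 0 for c in DhmrCategory},
    )
    with pytest.raises(DomainError):
        enrichment_test(zero)


# ----------------------------------------------------------- C→T filter


def test_filter_c_to_t_partition():
    variants = [
        Variant("chr1", 1, "C", "T"),
        Variant("chr1", 2, "G", "A"),
        Variant("chr1", 3, "A", "G"),
        Variant("chr1", 4, "C", "CA"),  # indel, never kept
    ]
    kept = filter_c_to_t(variants)
    assert [(v.ref, v.alt) for v in kept] == [("C", "T"), ("G", "A")]
    snvs = [v for v in variants if v.kind.value == "SNV"]
    assert len(kept) + len([v for v in snvs if v not in kept]) == len(snvs)


# ------------------------------------------------------- TET2 binding


def test_binding_enrichment_uniform_vs_exclusive():
    loci = loci_from(GAIN, LOSS, NOCH)
    uniform = IntervalSet(
        [GenomicInterval("chr1", s, s + 50) for s in (100, 300, 500)]
    )
    res = binding_enrichment(uniform, loci)
    assert res.test.p_value == pytest.approx(1.0)
    exclusive = IntervalSet(GAIN)
    res = binding_enrichment(exclusive, loci)
    assert res.coverage[DhmrCategory.HMC_GAIN] == (100, 0)
    assert res.coverage[DhmrCategory.NO_CHANGE] == (0, 100)
    assert res.test.p_value < 1e-10


def test_binding_enrichment_coverage_matches_mask_oracle():
    rng = np.random.default_rng(3)
    from oracles import random_interval_set

    lengths = {"chr1": 10_000}
    loci = loci_from(
        list(random_interval_set(rng, lengths, 5, 300).merge().intervals()),
        list(random_interval_set(rng, lengths, 5, 300).merge().intervals()),
        list(random_interval_set(rng, lengths, 5, 300).merge().intervals()),
    )
    # make categories disjoint for a meaningful oracle
    from tetmut.core import subtract

    gain = loci[DhmrCategory.HMC_GAIN].merge()
    loss = subtract(loci[DhmrCategory.HMC_LOSS_OR_MC_GAIN], gain)
    noch = subtract(
        subtract(loci[DhmrCategory.NO_CHANGE], gain), loss
    )
    loci = CategorizedLoci(
        {
            DhmrCategory.HMC_GAIN: gain,
            DhmrCategory.HMC_LOSS_OR_MC_GAIN: loss,
            DhmrCategory.NO_CHANGE: noch,
        }
    )
    tet2 = random_interval_set(rng, lengths, 8, 500)
    res = binding_enrichment(tet2, loci)
    mt = interval_set_mask(tet2.merge(), lengths)["chr1"]
    for cat, s in loci.loci.items():
        mc = interval_set_mask(s, lengths)["chr1"]
        assert res.coverage[cat] == (int((mc & mt).sum()), int((mc & ~mt).sum()))


def test_binding_mutation_overlap_edges_and_simulated_fraction(small_study):
    variants = [Variant("chr1", 150, "A", "G"), Variant("chr1", 700, "A", "G")]
    inside = IntervalSet([GenomicInterval("chr1", 0, 1000)])
    assert binding_mutation_overlap(variants, inside) == (2, 2)
    assert binding_mutation_overlap(variants, IntervalSet()) == (0, 2)

    # variants are placed uniformly within gained loci, so their TET2
    # overlap fraction recovers the realized covered-footprint fraction
    # within a binomial 95% CI
    from tetmut.core import intersect as core_intersect

    gain_variants = [
        v
        for v, t in zip(small_study.variants, small_study.variant_truth)
        if t.category == DhmrCategory.HMC_GAIN.value
    ]
    gain_set = IntervalSet(
        [
            t.interval
            for t in small_study.peak_truth
            if t.category is DhmrCategory.HMC_GAIN
        ]
    )
    expected = (
        core_intersect(gain_set, small_study.tet2_peaks).total_bp
        / gain_set.total_bp
    )
    n_overlap, n_total = binding_mutation_overlap(
        gain_variants, small_study.tet2_peaks
    )
    frac = n_overlap / n_total
    half_width = 1.96 * np.sqrt(expected * (1 - expected) / n_total)
    assert abs(frac - expected) < half_width + 0.02


# ------------------------------------------------- feature fold enrichment


def test_fold_enrichment_whole_genome_is_one():
    peaks = IntervalSet([GenomicInterval("chr1", 10, 20)])
    genome_feature = IntervalSet([GenomicInterval("chr1", 0, 1000)])
    assert feature_fold_enrichment(peaks, genome_feature, 1000) == pytest.approx(1.0)


def test_fold_enrichment_concentrated_feature():
    feature = IntervalSet([GenomicInterval("chr1", 0, 100)])
    peaks = IntervalSet([GenomicInterval("chr1", i, i + 5) for i in range(0, 100, 10)])
    assert feature_fold_enrichment(peaks, feature, 1000) == pytest.approx(10.0)
    with pytest.raises(DomainError):
        feature_fold_enrichment(peaks, IntervalSet(), 1000)


def test_fold_enrichment_null_near_one():
    """Random peaks vs a random feature: mean fold ~1 over replicates."""
    rng = np.random.default_rng(9)
    from oracles import random_interval_set

    lengths = {"chr1": 50_000}
    folds = []
    for _ in range(200):
        peaks = random_interval_set(rng, lengths, 20, 60)
        feature = random_interval_set(rng, lengths, 30, 2_000).merge()
        folds.append(feature_fold_enrichment(peaks, feature, 50_000))
    assert np.mean(folds) == pytest.approx(1.0, abs=0.1)
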