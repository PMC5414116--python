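import dataclasses

import numpy as np
import pytest

from tetmut.core import IntervalSet, find_cpg_sites
from tetmut.dhmr import DhmrCategory, classify_loci
from tetmut.enrichment import assign_variants
from tetmut.simulate import (
    AssayConfig,
    ConfigurationError,
    GenomeConfig,
    MutationConfig,
    PanelConfig,
    PeakConfig,
    SimulationConfig,
    simulate_cohort,
    simulate_fluctuation,
    simulate_genome,
    simulate_locus_panel,
    simulate_mutations,
    simulate_peaks,
    simulate_study,
)
from tetmut.spectrum import summarize_spectrum
from tetmut.dhmr import CategorizedLoci


# --------------------------------------------------------------------- genome


def test_genome_cpg_spacing_matches_configuration():
    cfg = SimulationConfig(
        seed=2, genome=GenomeConfig(n_chroms=1, chrom_length_bp=1_000_000)
    )
    genome = simulate_genome(cfg)
    sites = genome.cpg_positions["chr1"]
    gaps = np.diff(sites)
    assert abs(gaps.mean() - 100) / 100 < 0.05
    # CpG positions are genuine CG dinucleotides
    seq = genome.sequences["chr1"]
    for p in sites[:200]:
        assert seq[p : p + 2] == "CG"


def test_genome_deterministic_under_seed():
    cfg = SimulationConfig(seed=8, genome=GenomeConfig(n_chroms=1,
                                                       chrom_length_bp=20_000))
    assert simulate_genome(cfg).sequences == simulate_genome(cfg).sequences


def test_genome_tandem_cg_degenerate_case():
    cfg = SimulationConfig(
        seed=1,
        genome=GenomeConfig(n_chroms=1, chrom_length_bp=100,
                            cpg_mean_spacing_bp=2.0),
    )
    seq = simulate_genome(cfg).sequences["chr1"]
    assert seq[:98] == "CG" * 49


def test_genome_rejects_tiny_spacing():
    cfg = SimulationConfig(genome=GenomeConfig(cpg_mean_spacing_bp=1.0))
    with pytest.raises(ConfigurationError):
        simulate_genome(cfg)


# ---------------------------------------------------------------------- peaks


def test_peak_truth_recovered_by_classifier(small_study):
    mp = small_study.mark_peaks
    loci = classify_loci(
        mp[("5hmC", "WT")], mp[("5hmC", "KO")], mp[("5mC", "WT")], mp[("5mC", "KO")]
    )
    for t in small_study.peak_truth:
        mid = (t.interval.start + t.interval.end) // 2
        assert loci[t.category].contains(t.interval.chrom, mid)


def test_zero_peaks_in_category_yields_empty_category():
    cfg = SimulationConfig(
        seed=4,
        genome=GenomeConfig(n_chroms=1, chrom_length_bp=60_000),
        peaks=PeakConfig(n_peaks_per_category=0),
    )
    genome = simulate_genome(cfg)
    mark_peaks, truth = simulate_peaks(cfg, genome)
    assert truth == []
    assert all(not mp.peaks for mp in mark_peaks.values())


def test_infeasible_packing_raises():
    cfg = SimulationConfig(
        seed=4,
        genome=GenomeConfig(n_chroms=1, chrom_length_bp=5_000),
        peaks=PeakConfig(n_peaks_per_category=50, peak_length_mean_bp=1_000,
                         min_gap_bp=500),
    )
    genome = simulate_genome(cfg)
    with pytest.raises(ConfigurationError, match="cannot place"):
        simulate_peaks(cfg, genome)


# ------------------------------------------------------------------ mutations


def test_mutation_rate_ratio_recovers_multiplier(null_sim_parts):
    """With a 3× multiplier on gained loci, the empirical per-bp rate
    ratio lands within 3 ± 0.5 at n=600."""
    cfg, genome, truth = null_sim_parts
    cfg3 = dataclasses.replace(
        cfg,
        seed=77,
        mutations=dataclasses.replace(
            cfg.mutations,
            rate_multipliers={
                "no_change": 1.0,
                "hmc_loss_or_mc_gain": 1.0,
                "hmc_gain": 3.0,
                "background": 0.0,
            },
        ),
    )
    variants, vtruth = simulate_mutations(cfg3, genome, truth)
    by_cat = {c.value: IntervalSet() for c in DhmrCategory}
    footprints = {c.value: 0 for c in DhmrCategory}
    counts = {c.value: 0 for c in DhmrCategory}
    for t in truth:
        footprints[t.category.value] += t.interval.length
    for t in vtruth:
        counts[t.category] += 1
    rate = {c: counts[c] / footprints[c] for c in counts}
    baseline = (
        (counts["no_change"] + counts["hmc_loss_or_mc_gain"])
        / (footprints["no_change"] + footprints["hmc_loss_or_mc_gain"])
    )
    assert abs(rate["hmc_gain"] / baseline - 3.0) < 0.5


def test_mutation_spectrum_weight_recovery(null_sim_parts):
    cfg, genome, truth = null_sim_parts
    cfg_big = dataclasses.replace(
        cfg, seed=99,
        mutations=dataclasses.replace(cfg.mutations, n_total=5000),
    )
    variants, _ = simulate_mutations(cfg_big, genome, truth)
    s = summarize_spectrum(variants)
    props = s.class_proportions
    from tetmut.spectrum import SubstitutionClass

    assert props[SubstitutionClass.C_TO_T] == pytest.approx(0.35, abs=0.03)
    assert props[SubstitutionClass.T_TO_C] == pytest.approx(0.23, abs=0.03)
    assert s.proportions["transversions"] == pytest.approx(0.38, abs=0.03)


def test_mutation_truth_labels_consistent_with_vcf(small_study):
    for v, t in zip(small_study.variants, small_study.variant_truth):
        assert (v.chrom, v.pos) == (t.chrom, t.pos)
        # emitted REF matches the genome
        seq = small_study.genome.sequences[v.chrom]
        assert seq[v.pos - 1 : v.pos - 1 + len(v.ref)] == v.ref


def test_cpg_bias_raises_proximal_fraction(null_sim_parts):
    cfg, genome, truth = null_sim_parts
    biased = dataclasses.replace(
        cfg, seed=55,
        mutations=dataclasses.replace(cfg.mutations, cpg_proximity_bias=0.9),
    )
    _, vt_unbiased = simulate_mutations(dataclasses.replace(cfg, seed=55),
                                        genome, truth)
    _, vt_biased = simulate_mutations(biased, genome, truth)
    frac_unbiased = np.mean([t.near_cpg for t in vt_unbiased])
    frac_biased = np.mean([t.near_cpg for t in vt_biased])
    assert frac_biased > frac_unbiased + 0.2


def test_mutation_determinism(null_sim_parts):
    cfg, genome, truth = null_sim_parts
    v1, t1 = simulate_mutations(cfg, genome, truth)
    v2, t2 = simulate_mutations(cfg, genome, truth)
    assert v1 == v2 and t1 == t2


def test_bad_spectrum_weights_rejected(null_sim_parts):
    cfg, genome, truth = null_sim_parts
    bad = dataclasses.replace(
        cfg,
        mutations=dataclasses.replace(cfg.mutations,
                                      spectrum_weights={"C>T": 0.5}),
    )
    with pytest.raises(ConfigurationError, match="sum to 1"):
        simulate_mutations(bad, genome, truth)


# ------------------------------------------------------- cohort/panel/assay


def test_cohort_groups_and_determinism():
    cfg = SimulationConfig(seed=6)
    cohort = simulate_cohort(cfg)
    assert sum(s.tet2_status == "mutated" for s in cohort) == 41
    assert sum(s.tet2_status == "wild_type" for s in cohort) == 154
    assert cohort == simulate_cohort(cfg)
    means = {
        g: np.mean([s.n_mutations for s in cohort if s.tet2_status == g])
        for g in ("mutated", "wild_type")
    }
    assert means["mutated"] > means["wild_type"]


def test_panel_composition():
    cfg = SimulationConfig(seed=6)
    panel, elevated = simulate_locus_panel(cfg)
    assert len(panel) == 13 and len(elevated) == 7
    assert panel == simulate_locus_panel(cfg)[0]


def test_fluctuation_zero_frequency_and_determinism():
    cfg = SimulationConfig(seed=6)
    zero = simulate_fluctuation(cfg, true_frequency=0.0)
    assert zero.colonies_6tg == 0
    assert simulate_fluctuation(cfg) == simulate_fluctuation(cfg)


def test_config_from_dict_rejects_unknown_keys():
    with pytest.raises(ConfigurationError, match="bogus"):
        SimulationConfig.from_dict({"bogus": {}})
    with pytest.raises(ConfigurationError, match="nope"):
        SimulationConfig.from_dict({"genome": {"nope": 3}})
    cfg = SimulationConfig.from_dict(
        {"seed": 5, "genome": {"chrom_length_bp": 10_000}}
    )
    assert cfg.seed == 5 and cfg.genome.chrom_length_bp == 10_000
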