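# Methods

This document records the statistical model behind each module, the
default parameter choices and their rationale, deliberate methodological
decisions where more than one convention exists, and the scope and
limitations of the synthetic-data generator.

## Coordinates and formats

All internal coordinates are 0-based, half-open intervals. VCF input and
output are 1-based; the conversion happens only at the I/O boundary
(`tetmut.core.read_vcf` / `write_vcf`, via pysam). For interval
membership, an SNV occupies its (0-based) position; an indel is assigned
to the first changed base, i.e. the base after the VCF anchor. FASTA and
BED are read with hand-written parsers so that malformed lines are
reported with their line numbers; records on unknown chromosomes are a
validation error, not a silent drop.

Interval sets support `merge`, `intersect` and `subtract` implemented as
sorted numpy sweeps over (start, end) arrays. The test suite cross-checks
them against a per-base boolean-mask oracle on small chromosomes.

## Differential locus classification (`tetmut.dhmr`)

Inputs are four peak sets: 5hmC and 5mC, each in wild-type (WT) and
knockout (KO). A peak from condition A is considered *absent* in
condition B when its overlap with B's peaks is ≤ `min_overlap_fraction`
of its own length (default 0.0, i.e. any overlap disqualifies — a
whole-peak criterion, deliberately conservative so partial peak shifts do
not count as gains or losses). Categories:

- `HMC_GAIN`: merged 5hmC peaks gained in KO.
- `HMC_LOSS_OR_MC_GAIN`: merged union of 5hmC peaks lost in KO and 5mC
  peaks gained in KO, minus any base already in `HMC_GAIN` (gain takes
  precedence where the marks disagree).
- `NO_CHANGE`: 5hmC peaks present in both conditions, minus the two
  dynamic categories.

Bases outside all three categories are background and take no part in
the enrichment test.

## Footprint-normalized enrichment (`tetmut.enrichment`)

Each variant is assigned to the category containing its assigned base
(or counted as unassigned background). The enrichment test is a χ²
goodness-of-fit on the per-category variant counts with expected counts
proportional to each category's base-pair footprint, df = k − 1.
Rationale: raw counts conflate rate with footprint; normalizing by
footprint makes the null "uniform per-bp mutation rate across
categories". Background/unassigned variants are excluded because the
hypothesis concerns differential loci, and including the (much larger)
background footprint would let genome-wide rate differences dominate.
A C:G>T:A-restricted variant subset (`filter_c_to_t`) reruns the same
test on the class most tied to cytosine-modification chemistry.

TET2-binding association is a χ² test of independence on
covered/uncovered counts, at base resolution by default (peak resolution
by option): base resolution weights loci by their size, which matches
the footprint-normalized treatment used elsewhere.

## Spectrum and CpG proximity (`tetmut.spectrum`)

Substitutions are collapsed onto the pyrimidine strand (six classes
C>A, C>G, C>T, T>A, T>C, T>G); transitions are C>T and T>C. Indels are tabulated as +1 insertions, −1 deletions and
other.

A variant is *CpG-proximal* if the C of any CpG lies at or within
`window_bp` (default 30) of its assigned base; the window includes the
variant base itself and both strands of the CpG, so the catchment per
CpG is 2·window + 2 positions. Proximity is computed over all variants,
including indels, because the biological claim concerns mutation
placement generally, not a single class.

Null models for the expected proximal fraction:

- `exponential_gap` (default): CpG sites as a Poisson process with mean
  spacing λ; P(proximal) = 1 − exp(−(2w + 2)/λ). With w = 30 and
  λ = 100 this is 1 − e^(−0.62) ≈ 0.462. Default because inter-CpG
  distances in CpG-poor sequence are well approximated by an
  exponential, and the closed form makes the null auditable.
- `fixed_spacing`: deterministic spacing, min(1, (2w + 2)/λ) = 0.62 at
  the defaults — an upper-bound style null.
- `empirical_shuffle`: uniformly resampled positions on a supplied
  genome, scored against its actual CpG map (Monte Carlo, seeded).

## Fluctuation assay (`tetmut.fluctuation`)

Plating efficiency PE = colonies / cells on the non-selective plate;
mutation frequency = (6-TG-resistant colonies / cells plated under
selection) / PE. Replicate dishes are pooled (summed colonies over
summed cells) before normalization; per-dish frequencies are available
for dispersion summaries. Zero colonies on the PE plate is a domain
error; PE > 1 warns rather than fails (miscounting happens). Fold change
is a plain ratio of frequencies.

## Cohort and panel (`tetmut.cohort`)

Burden comparison between TET2-mutated and wild-type samples uses the
two-sided Wilcoxon rank-sum test: exact when the combined n ≤ 12 and
there are no ties, otherwise the normal approximation with tie
correction and continuity correction. Burden counts are heavily tied, so
the exact small-sample branch mainly serves the oracle tests.

Per-locus single-cell panels use the two-sided Fisher exact test
(minimum-likelihood rule) per locus on mutant/total cell counts in two
groups, with optional Bonferroni or Benjamini–Hochberg adjustment, a
pooled Fisher test on the summed counts, and the minimum per-locus p.
Loci with a zero-total group are skipped with a warning.

Lineage proportions are rounded half-up to one decimal below 10% and to
whole percent at or above 10%, matching standard reporting style.

## Synthetic data (`tetmut.simulate`)

Each stage (genome, peaks, mutations, cohort, assay, TET2 binding,
panel) draws from its own `numpy` `SeedSequence` substream spawned from
the master seed, so changing one stage's configuration never perturbs
another stage's draws.

Defaults and rationale:

- **Genome**: 2 chromosomes × 200 kb, GC 0.42, CpG sites planted with
  gaps 2 + Exponential(λ − 2) for a mean spacing of λ = 100 bp;
  accidental CG dinucleotides created by the background sequence are
  broken so the CpG map is exactly the planted set.
- **Peaks**: 30 per category, mean length 1 kb, minimum gap 200 bp.
  Loss-category peaks alternate between 5hmC-loss and 5mC-gain subtypes.
- **Mutations**: 600 variants, per-bp rate multipliers
  {no_change: 1, hmc_loss_or_mc_gain: 1, hmc_gain: 3, background: 1};
  category counts are multinomial with probabilities ∝ footprint ×
  multiplier; positions are then placed within the category, with a
  configurable fraction (`cpg_proximity_bias`, default 0.5) forced into
  CpG-proximal bases. At the default bias, roughly three quarters of
  variants land CpG-proximal (0.5 forced plus ≈ 0.46 of the remainder by
  chance), mimicking the strong CpG association reported for
  TET2-associated mutagenesis. Spectrum weights default to
  C>T 0.35, T>C 0.23, transversions 0.38 (split evenly across the four
  classes), +1 insertions 0.015 and −1 deletions 0.025 — i.e. 4% indels
  with deletions more common. Classes are drawn first and positions
  found by rejection sampling on reference compatibility.
- **Cohort**: n = 41 TET2-mutated vs n = 154 wild-type, negative
  binomial burdens (mean 10 in wild-type, ratio 1.5, dispersion 5).
- **Panel**: 13 loci, 7 elevated, 50 cells per group, mutant-cell
  fraction 0.02 baseline vs 0.40 elevated. The elevated fraction is set
  high enough that each truly elevated locus is individually detected
  with near-certain power at n = 50, so the panel recovers exactly the
  planted loci in almost every seed.
- **Assay**: true frequency 1e-5, plating efficiency 0.5, 3 × 5·10⁵
  cells under selection, 500 cells for PE; colony counts are Poisson,
  PE colonies binomial. The paired "knockdown" assay in
  `simulate_study` uses a 24-fold elevated true frequency.

Scope and limitations: the generator produces *category-labelled*
mutation placement, not a mechanistic mutational process — no
replication timing, transcription, strand bias or clonal structure; the
genome is i.i.d. background sequence plus planted CpGs, with none of the
repeat or compositional structure of a real genome; cohort burdens are
exchangeable within group (no covariates); assay counts ignore jackpot
(pre-existing mutant) dynamics, so frequencies, not Luria–Delbrück
rates, are the estimand. These choices keep every downstream statistic
analytically checkable against the generating parameters.

## Numerical choices

- Exact tests use scipy (`fisher_exact`, `mannwhitneyu(method="exact")`),
  verified in the test suite against integer-arithmetic enumeration
  oracles: every 2×2 table with total ≤ 30, and every tie-free rank-sum
  instance with combined n ≤ 12.
- χ² tests use `scipy.stats.chisquare` / `chi2_contingency` with Yates
  correction disabled, since footprints make expected counts large.
- Reports serialize with sorted keys and no timestamps; all randomness
  flows from explicit integer seeds (< 2³¹), so every artifact is
  byte-reproducible.
- Percent rounding uses decimal half-up (not banker's rounding) to match
  conventional reporting.
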