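# tetmut

Statistical toolkit for asking whether somatic mutations concentrate at
loci that gain 5-hydroxymethylcytosine (5hmC) when TET2 is lost, and for
the companion analyses that typically travel with that question: mutation
spectrum summaries, CpG-proximity null models, HPRT fluctuation-assay
frequencies, and patient-cohort burden comparisons.

## Background

TET2 oxidizes 5-methylcytosine (5mC) to 5hmC. When TET2 is inactivated —
a recurrent event in myeloid malignancies — the genomic distribution of
both marks shifts: some loci lose 5hmC or gain 5mC, while others
paradoxically *gain* 5hmC (through the activity of the remaining TET
enzymes). The central question this package addresses is whether somatic
mutations accumulate preferentially in those 5hmC-gain loci, beyond what
their genomic footprint alone would predict.

The analysis chain is:

1. **Differential locus classification** (`tetmut.dhmr`). From four peak
   sets (5hmC and 5mC, each in wild-type and knockout), classify loci into
   three categories: `HMC_GAIN` (5hmC appears in the knockout),
   `HMC_LOSS_OR_MC_GAIN` (5hmC disappears or 5mC appears), and
   `NO_CHANGE`. Gain takes precedence over loss where categories would
   overlap.
2. **Footprint-normalized enrichment** (`tetmut.enrichment`). Assign each
   variant to a category and run a χ² goodness-of-fit test with expected
   counts proportional to each category's base-pair footprint, so a
   category is only "enriched" if its per-bp mutation rate is elevated.
3. **Spectrum and CpG proximity** (`tetmut.spectrum`). Pyrimidine-collapsed
   substitution classes (C>A … T>G), ±1 indels, transition/transversion
   fractions, and the fraction of mutations at or within ±30 bp of a CpG
   site — compared against analytic or resampling null models of CpG
   placement.
4. **Orthogonal functional and cohort evidence** (`tetmut.fluctuation`,
   `tetmut.cohort`). HPRT 6-thioguanine fluctuation-assay mutation
   frequencies with plating-efficiency normalization; rank-sum burden
   comparison between TET2-mutated and wild-type patient cohorts; and
   per-locus Fisher tests for single-cell amplicon panels.

A truth-labelled synthetic study generator (`tetmut.simulate`) ties the
pieces together and powers the test suite: every downstream statistic can
be checked against the parameters that generated the data.

## Worked example

```python
from tetmut.pipeline import analyze
from tetmut.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=7))
mp = study.mark_peaks
report = analyze(
    study.genome,
    mp[("5hmC", "WT")].peaks, mp[("5hmC", "KO")].peaks,
    mp[("5mC", "WT")].peaks, mp[("5mC", "KO")].peaks,
    study.variants, tet2_peaks=study.tet2_peaks,
)
```

With the default configuration (two 200 kb chromosomes, mean CpG spacing
100 bp, 600 variants, a 3× per-bp rate multiplier in 5hmC-gain loci) this
prints, via `examples/end_to_end_pipeline.py`:

```
mutations per Mb by locus category:
                hmc_gain:   3841.2
     hmc_loss_or_mc_gain:   1336.7
               no_change:   1103.4
footprint-normalized chi-square: statistic=67.2, df=2, p=2.54e-15
CpG proximity (±30 bp): observed 74.2% vs 46.2% expected under the exponential-gap null
mutations in differential loci overlapping TET2 peaks: 81/191
```

The per-Mb rate in `hmc_gain` loci is about 3× the other categories —
recovering the planted effect — and the observed CpG proximity far
exceeds the 46.2% expected by chance under exponential CpG spacing.

More short narrative scripts live in `examples/`:

- `end_to_end_pipeline.py` — the run above.
- `spectrum_and_cpg_null.py` — substitution-class proportions and the
  three CpG null models (`exponential_gap`, `fixed_spacing`,
  `empirical_shuffle`).
- `fluctuation_assay.py` — 6-TG colony counts to mutation frequencies and
  fold change.
- `cohort_and_panel.py` — cohort burden comparison (n=41 vs 154) and a
  13-locus single-cell panel with per-locus Fisher tests.

## Command line

The same pipeline is exposed as a thin CLI:

```
tetmut simulate --seed 7 --out study/        # FASTA+BED+VCF+TSV+truth.json
tetmut analyze --fasta study/genome.fa \
    --hmc-wt study/hmc_wt.bed --hmc-ko study/hmc_ko.bed \
    --mc-wt study/mc_wt.bed --mc-ko study/mc_ko.bed \
    --vcf study/mutations.vcf --tet2-bed study/tet2.bed --out report.json
tetmut classify-dhmr ...   # per-category BED files + footprint table
tetmut spectrum ...        # spectrum + CpG proximity for a VCF
tetmut cohort --tsv study/cohort.tsv   # or a panel.tsv
tetmut assay --tsv study/assay.tsv
```

All reports are JSON with sorted keys and no timestamps, so identical
inputs regenerate byte-identical output.

## Conventions

- Coordinates are 0-based half-open internally; VCF positions are 1-based
  at the I/O boundary only. The base a variant is assigned to is the
  variant position for SNVs and the first changed base for indels.
- Two-sided Fisher tests use the minimum-likelihood rule; rank-sum tests
  are exact for combined n ≤ 12 without ties, asymptotic with tie
  correction and continuity correction otherwise.

See `docs/methods.md` for the full model description, parameter
rationale and limitations.

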