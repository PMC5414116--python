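"""End-to-end orchestration: fixture writing, the analyze pipeline and
machine-readable reports.

Reports are plain dictionaries serialised as JSON with sorted keys and no
timestamps, so identical inputs and options regenerate byte-identical
output.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .cohort import (
    CohortSample,
    LocusCellCounts,
    burden_compare,
    per_locus_fisher,
)
from .core import (
    IntervalSet,
    ReferenceGenome,
    ValidationError,
    Variant,
    read_bed,
    read_fasta,
    read_vcf,
    write_bed,
    write_fasta,
    write_vcf,
)
from .dhmr import CategorizedLoci, Condition, DhmrCategory, Mark, MarkPeaks, classify_loci
from .enrichment import (
    assign_variants,
    binding_enrichment,
    binding_mutation_overlap,
    enrichment_test,
    filter_c_to_t,
)
from .fluctuation import FluctuationAssayInput, fold_change, mutation_frequency
from .simulate import SimulatedStudy, SimulationConfig
from .spectrum import CpGNullModel, cpg_proximity, expected_cpg_fraction, summarize_spectrum
from .stats import DomainError, TestResult

__all__ = [
    "write_study",
    "analyze",
    "cohort_report",
    "panel_report",
    "assay_report",
    "read_cohort_tsv",
    "read_panel_tsv",
    "read_assay_tsv",
    "write_report",
]

_MARK_FILES = {
    ("5hmC", "WT"): "hmc_wt.bed",
    ("5hmC", "KO"): "hmc_ko.bed",
    ("5mC", "WT"): "mc_wt.bed",
    ("5mC", "KO"): "mc_ko.bed",
}


def write_study(study: SimulatedStudy, outdir: str | Path) -> Path:
    """Write a simulated study as standard-format files plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(study.genome, outdir / "genome.fa")
    for key, fname in _MARK_FILES.items():
        write_bed(study.mark_peaks[key].peaks, outdir / fname)
    write_bed(study.tet2_peaks, outdir / "tet2.bed")
    write_vcf(study.variants, outdir / "mutations.vcf", genome=study.genome)
    pd.DataFrame(
        [(s.sample_id, s.tet2_status, s.n_mutations) for s in study.cohort],
        columns=["sample_id", "tet2_status", "n_mutations"],
    ).to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    panel_rows = []
    for locus in study.panel:
        for group in sorted(locus.counts):
            m, t = locus.counts[group]
            panel_rows.append((locus.locus_id, group, m, t))
    pd.DataFrame(
        panel_rows, columns=["locus_id", "group", "n_mutant", "n_total"]
    ).to_csv(outdir / "panel.tsv", sep="\t", index=False)
    assay_rows = [
        ("control",) + _assay_tuple(study.assay_control),
        ("tet2_kd",) + _assay_tuple(study.assay_test),
    ]
    pd.DataFrame(
        assay_rows,
        columns=[
            "condition",
            "cells_plated_selection",
            "colonies_6tg",
            "cells_plated_pe",
            "colonies_pe",
        ],
    ).to_csv(outdir / "assay.tsv", sep="\t", index=False)
    truth = {
        "seed": study.config.seed,
        "peaks": [
            {
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "category": t.category.value,
                "subtype": t.subtype,
            }
            for t in study.peak_truth
        ],
        "variants": [dataclasses.asdict(t) for t in study.variant_truth],
        "panel_elevated": study.panel_elevated,
        "cohort": dataclasses.asdict(study.config.cohort),
        "assay": dataclasses.asdict(study.config.assay),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return outdir


def _assay_tuple(a: FluctuationAssayInput):
    return (
        a.cells_plated_selection,
        a.colonies_6tg,
        a.cells_plated_pe,
        a.colonies_pe,
    )


# ---------------------------------------------------------------------------
# Analyze pipeline
# ---------------------------------------------------------------------------


def _test_dict(t: TestResult) -> Dict:
    return {
        "p_value": t.p_value,
        "statistic": t.statistic,
        "df": t.df,
        "method": t.method,
    }


def analyze(
    genome: ReferenceGenome,
    hmc_wt: IntervalSet,
    hmc_ko: IntervalSet,
    mc_wt: IntervalSet,
    mc_ko: IntervalSet,
    variants: Sequence[Variant],
    tet2_peaks: Optional[IntervalSet] = None,
    window_bp: int = 30,
    cpg_mean_spacing_bp: float = 100.0,
    min_overlap_fraction: float = 0.0,
) -> Dict:
    """Classify loci, assign and test variants, summarise spectrum and
    CpG proximity; returns the run report as a plain dict."""
    _check_chroms(genome, [hmc_wt, hmc_ko, mc_wt, mc_ko, tet2_peaks], variants)
    loci = classify_loci(
        MarkPeaks(Condition.WT, Mark.HMC, hmc_wt),
        MarkPeaks(Condition.KO, Mark.HMC, hmc_ko),
        MarkPeaks(Condition.WT, Mark.MC, mc_wt),
        MarkPeaks(Condition.KO, Mark.MC, mc_ko),
        min_overlap_fraction=min_overlap_fraction,
    )
    report: Dict = {
        "provenance": {
            "tetmut_version": __version__,
            "options": {
                "window_bp": window_bp,
                "cpg_mean_spacing_bp": cpg_mean_spacing_bp,
                "min_overlap_fraction": min_overlap_fraction,
            },
        },
        "footprints_bp": {c.value: bp for c, bp in loci.footprint_bp.items()},
    }
    counts = assign_variants(variants, loci)
    report["category_counts"] = {
        "n_variants": {c.value: n for c, n in counts.n_variants.items()},
        "unassigned_variants": counts.unassigned_variants,
        "rates_per_mb": {c.value: r for c, r in counts.rates_per_mb.items()},
    }
    if not variants:
        report["enrichment"] = {"status": "not_applicable", "reason": "no variants"}
        report["spectrum"] = {"status": "not_applicable", "reason": "no variants"}
        report["cpg_proximity"] = {"status": "not_applicable", "reason": "no variants"}
    else:
        try:
            enr = enrichment_test(counts)
            report["enrichment"] = {"test": _test_dict(enr.test)}
        except DomainError as exc:
            report["enrichment"] = {"status": "not_applicable", "reason": str(exc)}
        ct = filter_c_to_t(variants)
        if ct:
            try:
                enr_ct = enrichment_test(assign_variants(ct, loci))
                report["enrichment_c_to_t"] = {
                    "n_variants": len(ct),
                    "test": _test_dict(enr_ct.test),
                }
            except DomainError as exc:
                report["enrichment_c_to_t"] = {
                    "status": "not_applicable", "reason": str(exc),
                }
        spec = summarize_spectrum(variants)
        report["spectrum"] = {
            "proportions": spec.proportions,
            "class_counts": {c.value: n for c, n in spec.class_counts.items()},
        }
        prox = cpg_proximity(variants, genome, window_bp=window_bp)
        expected = expected_cpg_fraction(
            CpGNullModel(mean_spacing_bp=cpg_mean_spacing_bp, window_bp=window_bp)
        )
        report["cpg_proximity"] = {
            "window_bp": window_bp,
            "n_total": prox.n_total,
            "n_proximal": prox.n_proximal,
            "fraction": prox.fraction,
            "expected_fraction_null": expected,
        }
    if tet2_peaks is not None:
        try:
            be = binding_enrichment(tet2_peaks, loci)
            report["tet2_binding"] = {
                "coverage_bp": {c.value: list(v) for c, v in be.coverage.items()},
                "test": _test_dict(be.test),
            }
        except DomainError as exc:
            report["tet2_binding"] = {"status": "not_applicable", "reason": str(exc)}
        in_loci = [
            v
            for v in variants
            if loci.category_of(v.chrom, v.assigned_base) is not None
        ]
        n_overlap, n_total = binding_mutation_overlap(in_loci, tet2_peaks)
        report["tet2_mutation_overlap"] = {
            "n_overlapping": n_overlap,
            "n_in_loci": n_total,
        }
    return report


def _check_chroms(genome, interval_sets, variants) -> None:
    known = set(genome.chroms)
    offenders = []
    for s in interval_sets:
        if s is None:
            continue
        offenders += [c for c in s.chroms if c not in known]
    offenders += sorted({v.chrom for v in variants} - known)
    if offenders:
        raise ValidationError(
            f"chromosome names absent from the genome: {sorted(set(offenders))}"
        )


def analyze_files(
    fasta: str | Path,
    hmc_wt: str | Path,
    hmc_ko: str | Path,
    mc_wt: str | Path,
    mc_ko: str | Path,
    vcf: str | Path,
    tet2_bed: Optional[str | Path] = None,
    **options,
) -> Dict:
    genome = read_fasta(fasta)
    return analyze(
        genome,
        read_bed(hmc_wt),
        read_bed(hmc_ko),
        read_bed(mc_wt),
        read_bed(mc_ko),
        read_vcf(vcf, genome=genome),
        tet2_peaks=read_bed(tet2_bed) if tet2_bed else None,
        **options,
    )


# ---------------------------------------------------------------------------
# Cohort / panel / assay reports
# ---------------------------------------------------------------------------


def read_cohort_tsv(path: str | Path) -> List[CohortSample]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "tet2_status", "n_mutations"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"cohort table missing column(s) {sorted(missing)}")
    return [
        CohortSample(str(r.sample_id), str(r.tet2_status), int(r.n_mutations))
        for r in df.itertuples()
    ]


def read_panel_tsv(path: str | Path) -> List[LocusCellCounts]:
    df = pd.read_csv(path, sep="\t")
    required = {"locus_id", "group", "n_mutant", "n_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"panel table missing column(s) {sorted(missing)}")
    loci = []
    for locus_id, sub in df.groupby("locus_id", sort=True):
        counts = {
            str(r.group): (int(r.n_mutant), int(r.n_total)) for r in sub.itertuples()
        }
        loci.append(LocusCellCounts(str(locus_id), counts))
    return loci


def read_assay_tsv(path: str | Path) -> Dict[str, FluctuationAssayInput]:
    df = pd.read_csv(path, sep="\t")
    required = {
        "condition",
        "cells_plated_selection",
        "colonies_6tg",
        "cells_plated_pe",
        "colonies_pe",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"assay table missing column(s) {sorted(missing)}")
    return {
        str(r.condition): FluctuationAssayInput(
            int(r.cells_plated_selection),
            int(r.colonies_6tg),
            int(r.cells_plated_pe),
            int(r.colonies_pe),
        )
        for r in df.itertuples()
    }


def cohort_report(cohort: Sequence[CohortSample]) -> Dict:
    res = burden_compare(cohort)
    return {
        "test": _test_dict(res.test),
        "medians": res.medians,
        "iqr": {g: list(v) for g, v in res.iqr.items()},
        "n": res.n,
    }


def panel_report(
    loci: Sequence[LocusCellCounts], alpha: float = 0.05,
    correction: Optional[str] = None,
) -> Dict:
    res = per_locus_fisher(loci, alpha=alpha, correction=correction)
    return {
        "per_locus_p": {lid: t.p_value for lid, t in res.per_locus.items()},
        "n_significant": res.n_significant,
        "alpha": res.alpha,
        "pooled": _test_dict(res.pooled),
        "min_p": res.min_p,
    }


def assay_report(
    assays: Dict[str, FluctuationAssayInput], control: str = "control"
) -> Dict:
    if control not in assays:
        raise ValidationError(f"control condition {control!r} not in assay table")
    results = {name: mutation_frequency(a) for name, a in assays.items()}
    ctrl_f = results[control].mutation_frequency
    out: Dict = {"control": control, "conditions": {}}
    for name, r in results.items():
        entry = {
            "plating_efficiency": r.plating_efficiency,
            "mutation_frequency": r.mutation_frequency,
        }
        if name != control and ctrl_f > 0:
            entry["fold_change_vs_control"] = fold_change(
                r.mutation_frequency, ctrl_f
            )
        out["conditions"][name] = entry
    return out


def write_report(report: Dict, path: str | Path) -> None:
    text = json.dumps(report, indent=1, sort_keys=True)
    Path(path).write_text(text + "\n")


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
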