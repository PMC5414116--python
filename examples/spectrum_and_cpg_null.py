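"""Summarize a simulated mutation spectrum and compare the observed CpG
proximity of mutations against three null models of CpG placement."""
from tetmut.simulate import SimulationConfig, simulate_study
from tetmut.spectrum import (
    CpGNullModel,
    cpg_proximity,
    expected_cpg_fraction,
    summarize_spectrum,
)

study = simulate_study(SimulationConfig(seed=11))
spec = summarize_spectrum(study.variants)

print(f"{spec.n_total} variants")
for cls, n in sorted(spec.class_counts.items(), key=lambda kv: kv[0].value):
    print(f"  {cls.value}: {n:4d}  ({n / spec.n_total:.1%})")
print(f"  transitions {spec.proportions['transitions']:.1%}, "
      f"transversions {spec.proportions['transversions']:.1%}, "
      f"+1 ins {spec.n_plus1_insertions}, -1 del {spec.n_minus1_deletions}")

prox = cpg_proximity(study.variants, study.genome, window_bp=30)
print(f"\nobserved at/within ±30 bp of a CpG: {prox.fraction:.1%} "
      f"({prox.n_proximal}/{prox.n_total})")
for model in ("exponential_gap", "fixed_spacing", "empirical_shuffle"):
    null = CpGNullModel(mean_spacing_bp=100.0, window_bp=30, model=model)
    e = expected_cpg_fraction(null, genome=study.genome, seed=0)
    print(f"  expected under {model:>17}: {e:.1%}")
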