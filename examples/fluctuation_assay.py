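"""HPRT 6-thioguanine fluctuation assay: estimate mutation frequency in a
control and a TET2-knockdown condition and report the fold change."""
from tetmut.fluctuation import fold_change, mutation_frequency
from tetmut.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=5))
control = mutation_frequency(study.assay_control)
knockdown = mutation_frequency(study.assay_test)

for name, res, raw in (
    ("control", control, study.assay_control),
    ("TET2 knockdown", knockdown, study.assay_test),
):
    print(f"{name}: {raw.colonies_6tg} 6-TG-resistant colonies from "
          f"{raw.cells_plated_selection:,} cells, "
          f"plating efficiency {res.plating_efficiency:.2f} -> "
          f"mutation frequency {res.mutation_frequency:.2e}")
fc = fold_change(knockdown.mutation_frequency, control.mutation_frequency)
print(f"fold change vs control: {fc:.1f}x")
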