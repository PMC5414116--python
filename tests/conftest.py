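import dataclasses

import numpy as np
import pytest

from tetmut.simulate import (
    GenomeConfig,
    MutationConfig,
    PeakConfig,
    SimulationConfig,
    simulate_genome,
    simulate_peaks,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact study: 1 chromosome, 150 kb, 10 peaks per category."""
    return SimulationConfig(
        seed=11,
        genome=GenomeConfig(n_chroms=1, chrom_length_bp=150_000),
        peaks=PeakConfig(n_peaks_per_category=10, peak_length_mean_bp=800,
                         min_gap_bp=300),
        mutations=MutationConfig(n_total=400),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def null_sim_parts():
    """One genome + peak truth reused across null-calibration replicates."""
    cfg = SimulationConfig(
        seed=29,
        genome=GenomeConfig(n_chroms=1, chrom_length_bp=150_000),
        peaks=PeakConfig(n_peaks_per_category=10, peak_length_mean_bp=1000,
                         min_gap_bp=300),
        mutations=MutationConfig(
            n_total=600,
            rate_multipliers={
                "no_change": 1.0,
                "hmc_loss_or_mc_gain": 1.0,
                "hmc_gain": 1.0,
                "background": 0.0,
            },
            cpg_proximity_bias=0.0,
        ),
    )
    genome = simulate_genome(cfg)
    _, truth = simulate_peaks(cfg, genome)
    return cfg, genome, truth


def reseed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return dataclasses.replace(cfg, seed=seed)
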