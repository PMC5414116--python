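"""HPRT 6-thioguanine fluctuation-assay frequencies.

Loss of HPRT makes cells resistant to 6-thioguanine (6-TG), so resistant
colonies report forward mutations.  The mutation frequency is the number
of 6-TG-resistant colonies per plated cell, normalized by the plating
efficiency (the colony-forming fraction measured without selection).
Replicate dishes are pooled by default (sum of colonies over sum of
cells); a per-dish mode reports mean ± s.d. across dishes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .stats import DomainError

__all__ = [
    "FluctuationAssayInput",
    "FluctuationResult",
    "plating_efficiency",
    "mutation_frequency",
    "per_dish_frequencies",
    "fold_change",
]


@dataclass(frozen=True)
class FluctuationAssayInput:
    """Pooled colony counts for one condition.

    ``cells_plated_selection`` is the total across dishes (e.g. 5e5 cells
    in each of three dishes → 1.5e6); ``cells_plated_pe`` is the number
    plated without 6-TG for the plating-efficiency control.
    """

    cells_plated_selection: int
    colonies_6tg: int
    cells_plated_pe: int
    colonies_pe: int

    def __post_init__(self) -> None:
        if self.cells_plated_selection <= 0 or self.cells_plated_pe <= 0:
            raise DomainError("cells plated must be > 0")
        if self.colonies_6tg < 0 or self.colonies_pe < 0:
            raise DomainError("colony counts must be >= 0")


@dataclass(frozen=True)
class FluctuationResult:
    plating_efficiency: float
    mutation_frequency: float


def plating_efficiency(colonies_pe: int, cells_plated_pe: int) -> float:
    """Colony-forming fraction without selection; warns (does not fail)
    when counts exceed cells plated."""
    if cells_plated_pe <= 0:
        raise DomainError("cells plated must be > 0")
    if colonies_pe == 0:
        raise DomainError(
            "zero plating-efficiency colonies: mutation frequency undefined"
        )
    pe = colonies_pe / cells_plated_pe
    if pe > 1:
        warnings.warn(
            f"plating efficiency {pe:.3g} > 1; check colony counts",
            stacklevel=2,
        )
    return pe


def mutation_frequency(inp: FluctuationAssayInput) -> FluctuationResult:
    """(6-TG colonies / cells plated) / plating efficiency."""
    pe = plating_efficiency(inp.colonies_pe, inp.cells_plated_pe)
    freq = (inp.colonies_6tg / inp.cells_plated_selection) / pe
    return FluctuationResult(plating_efficiency=pe, mutation_frequency=freq)


def per_dish_frequencies(
    colonies_per_dish: Sequence[int],
    cells_per_dish: int,
    pe: float,
) -> Tuple[float, float, np.ndarray]:
    """Per-dish frequencies at a shared plating efficiency: (mean, s.d., all)."""
    if pe <= 0:
        raise DomainError("plating efficiency must be > 0")
    if cells_per_dish <= 0:
        raise DomainError("cells per dish must be > 0")
    freqs = np.asarray(colonies_per_dish, dtype=float) / cells_per_dish / pe
    return float(freqs.mean()), float(freqs.std(ddof=1) if len(freqs) > 1 else 0.0), freqs


def fold_change(freq_test: float, freq_control: float) -> float:
    if freq_control <= 0:
        raise DomainError("control frequency must be > 0")
    return freq_test / freq_control
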