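"""Independent brute-force oracles used to validate the fast paths."""
from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Dict, Sequence

import numpy as np

from tetmut.core import IntervalSet


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full hypergeometric enumeration
    (minimum-likelihood rule), in exact integer arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def weight(x: int) -> int:
        return comb(r1, x) * comb(r2, c1 - x)

    obs = weight(a)
    total = sum(
        w
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if (w := weight(x)) <= obs
    )
    return total / denom


def ranksum_two_sided_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled observations to the first group (ties not supported)."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    nx = len(x)
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    us = [
        sum(idx) - nx * (nx + 1) / 2
        for idx in combinations(range(1, len(pooled) + 1), nx)
    ]
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, float(p))


def interval_set_mask(s: IntervalSet, lengths: Dict[str, int]) -> Dict[str, np.ndarray]:
    """Per-base boolean membership masks for every chromosome."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}
    for iv in s.intervals():
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def mask_to_total_bp(masks: Dict[str, np.ndarray]) -> int:
    return int(sum(m.sum() for m in masks.values()))


def random_interval_set(
    rng: np.random.Generator, lengths: Dict[str, int], n: int, max_len: int = 400
) -> IntervalSet:
    from tetmut.core import GenomicInterval

    ivals = []
    chroms = list(lengths)
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, lengths[chrom] - 1))
        end = min(lengths[chrom], start + 1 + int(rng.integers(0, max_len)))
        ivals.append(GenomicInterval(chrom, start, end))
    return IntervalSet(ivals)
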