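"""Four-taxon Patterson's D with weighted block-jackknife standard errors.

Pattern mass is frequency-based: per polarized site,
ABBA = (1-p1)*p2*p3 and BABA = p1*(1-p2)*p3 with p the derived-allele
frequency in each group (the outgroup fixes the ancestral allele, so its
derived frequency is 0). Single-sample groups reduce to 0/1 frequencies
and reproduce count-based D. The delete-one jackknife over contiguous
blocks uses Busing-style weights proportional to informative-site mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .variant_io import HaplotypeSet, PopMap


@dataclass
class QuartetConfig:
    p1: object
    p2: object
    p3: object
    outgroup: object
    block_size_bp: int = 5_000_000

    def groups(self) -> tuple:
        return (self.p1, self.p2, self.p3, self.outgroup)


@dataclass
class DResult:
    d: float
    se: float
    z: float
    n_blocks: int
    sum_abba: float
    sum_baba: float
    n_informative: int
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = math.isfinite(self.z) and abs(self.z) >= 3.0


def d_statistic(haps: HaplotypeSet, popmap: PopMap, quartet: QuartetConfig) -> DResult:
    """Patterson's D for (((P1,P2),P3),O) with block-jackknife Z.

    Sites are polarized by the outgroup: sites where the outgroup group is
    polymorphic, or where any group is entirely missing, are skipped.
    D = sum(ABBA - BABA) / sum(ABBA + BABA); Z = D / SE with SE from the
    weighted delete-one block jackknife (blocks of ``block_size_bp``).
    Raises when no site carries ABBA/BABA mass; with < 2 non-empty blocks
    SE and Z are NaN (flagged unavailable).
    """
    rows = [haps.population_rows(popmap, *_as_tuple(g)) for g in quartet.groups()]
    if any(len(r) == 0 for r in rows):
        raise ValueError("all four quartet groups must be non-empty")
    num_per_block: dict = {}
    den_per_block: dict = {}
    cnt_per_block: dict = {}
    n_informative = 0
    for j in range(haps.n_sites):
        freqs = [haps.allele_frequency(r, j) for r in rows]
        if any(math.isnan(f) for f in freqs):
            continue
        p_o = freqs[3]
        if 0.0 < p_o < 1.0:
            continue  # outgroup polymorphic: cannot polarize
        if p_o == 0.0:
            p1, p2, p3 = freqs[0], freqs[1], freqs[2]
        else:  # outgroup fixed for alt: ref is derived
            p1, p2, p3 = 1 - freqs[0], 1 - freqs[1], 1 - freqs[2]
        abba = (1 - p1) * p2 * p3
        baba = p1 * (1 - p2) * p3
        if abba == 0.0 and baba == 0.0:
            continue
        n_informative += 1
        key = (haps.chroms[j], (int(haps.positions[j]) - 1) // quartet.block_size_bp)
        num_per_block[key] = num_per_block.get(key, 0.0) + (abba - baba)
        den_per_block[key] = den_per_block.get(key, 0.0) + (abba + baba)
        cnt_per_block[key] = cnt_per_block.get(key, 0) + 1

    total_num = sum(num_per_block.values())
    total_den = sum(den_per_block.values())
    sum_abba = (total_den + total_num) / 2.0
    sum_baba = (total_den - total_num) / 2.0
    if total_den == 0.0:
        raise ValueError("no ABBA/BABA-informative sites: D undefined")
    d = total_num / total_den

    keys = list(num_per_block)
    g = len(keys)
    if g < 2:
        return DResult(d, math.nan, math.nan, g, sum_abba, sum_baba, n_informative)

    weights = np.array([cnt_per_block[k] for k in keys], dtype=float)
    n_tot = weights.sum()
    d_minus = np.array(
        [
            (total_num - num_per_block[k]) / (total_den - den_per_block[k])
            if (total_den - den_per_block[k]) != 0.0
            else 0.0
            for k in keys
        ]
    )
    # Busing et al. weighted delete-one jackknife
    h = n_tot / weights
    theta_jack = g * d - float(((1.0 - weights / n_tot) * d_minus).sum())
    pseudo = h * d - (h - 1.0) * d_minus
    var = float((((pseudo - theta_jack) ** 2) / (h - 1.0)).sum()) / g
    se = math.sqrt(var) if var > 0 else math.nan
    z = d / se if (se and se > 0) else math.nan
    return DResult(d, se, z, g, sum_abba, sum_baba, n_informative)


def _as_tuple(pop):
    return tuple(pop) if isinstance(pop, (tuple, list)) else (pop,)
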