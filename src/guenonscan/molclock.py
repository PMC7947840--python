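"""Synonymous-distance (Nei-Gojobori 1986) estimation and the neutral-rate
formula r = Ks / (2 t).

NG86 counts synonymous sites per codon as the fraction of the three
possible changes at each position that are synonymous (changes creating a
stop codon count as nonsynonymous for site counting); observed
differences between codons differing at several positions are averaged
over all mutational pathways, excluding pathways that pass through a stop
codon. The Jukes-Cantor correction Ks = -3/4 ln(1 - 4 pS / 3) maps the
proportion of synonymous differences to a distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
STOP_CODONS = set(standard_dna_table.stop_codons)
CODON_TABLE = dict(standard_dna_table.forward_table)


def _aa(codon: str):
    """Amino acid for a codon; None for stops."""
    return None if codon in STOP_CODONS else CODON_TABLE[codon]


@dataclass
class KsResult:
    s_sites: float  # mean synonymous site count over the two sequences
    n_sites: float
    sd: float  # pathway-averaged synonymous differences
    nd: float
    ps: float  # Sd / S
    pn: float
    ks: float  # Jukes-Cantor-corrected synonymous distance
    ka: float
    n_codons: int


@dataclass
class RateEstimate:
    r_per_year: float
    t_years: float
    g_years: float
    r_per_generation: float


def synonymous_site_fraction(codon: str) -> tuple:
    """(synonymous, nonsynonymous) site counts for one sense codon."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    s = 0.0
    for i in range(3):
        syn = 0
        for b in BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if _aa(mutant) is not None and _aa(mutant) == _aa(codon):
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _codon_differences(codon_a: str, codon_b: str) -> tuple:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    All orderings of the differing positions are enumerated; pathways
    that pass through a stop codon are excluded. If every pathway is
    blocked, stop-passing pathways are used with stop steps counted as
    nonsynonymous (degenerate case; cannot occur between sense codons
    differing at a single position).
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = codon_a
        sd = nd = 0.0
        for i in order:
            nxt = cur[:i] + codon_b[i] + cur[i + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                nd += 1.0
            elif _aa(nxt) == _aa(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [p for p in (walk(o, False) for o in permutations(diff)) if p is not None]
    if not paths:
        paths = [walk(o, True) for o in permutations(diff)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ks_ng86(cds_a: str, cds_b: str) -> KsResult:
    """NG86 synonymous/nonsynonymous distances between two aligned CDSs.

    Sequences must be equal-length, gap-free, in frame and free of stop
    codons. Raises when pS >= 0.75 (Jukes-Cantor correction undefined).
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must be equal length")
    if len(cds_a) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    if any(c not in BASES for c in cds_a + cds_b):
        raise ValueError("sequences must be gap-free A/C/G/T")
    n_codons = len(cds_a) // 3
    s_a = s_b = sd = nd = 0.0
    for k in range(n_codons):
        ca, cb = cds_a[3 * k : 3 * k + 3], cds_b[3 * k : 3 * k + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon at codon {k + 1}")
        sa, _ = synonymous_site_fraction(ca)
        sb, _ = synonymous_site_fraction(cb)
        s_a += sa
        s_b += sb
        d_s, d_n = _codon_differences(ca, cb)
        sd += d_s
        nd += d_n
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    if ps >= 0.75:
        raise ValueError(f"pS = {ps:.3f} >= 0.75: Ks undefined")
    ks = -0.75 * math.log(1.0 - 4.0 * ps / 3.0)
    ka = -0.75 * math.log(1.0 - 4.0 * pn / 3.0) if pn < 0.75 else math.inf
    return KsResult(s_sites, n_sites, sd, nd, ps, pn, ks, ka, n_codons)


def neutral_rate(ks: float, t_years: float, g_years: float = 8.5) -> RateEstimate:
    """Neutral substitution rate r = Ks / (2 t), scaled per generation.

    ``t_years`` is the divergence time of the orthologue pair;
    ``g_years`` the generation time used for the per-generation rate.
    """
    if t_years <= 0:
        raise ValueError("divergence time must be positive")
    r = ks / (2.0 * t_years)
    return RateEstimate(
        r_per_year=r, t_years=t_years, g_years=g_years, r_per_generation=r * g_years
    )


def ks_from_fasta_pairs(path_a, path_b) -> list:
    """NG86 results for records paired by order in two FASTA files."""
    from Bio import SeqIO

    recs_a = list(SeqIO.parse(str(path_a), "fasta"))
    recs_b = list(SeqIO.parse(str(path_b), "fasta"))
    if len(recs_a) != len(recs_b):
        raise ValueError("FASTA files must contain the same number of records")
    return [
        (ra.id, rb.id, ks_ng86(str(ra.seq), str(rb.seq))) for ra, rb in zip(recs_a, recs_b)
    ]
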