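"""Per-window nucleotide diversity, dxy, Weir-Cockerham Fst and PBS.

Conventions: window Fst is the ratio-of-sums (weighted) Weir & Cockerham
(1984) estimator; negative window values are clamped to 0; Fst values are
capped below 1 before the log transform T = -ln(1 - Fst); PBS for focal
branch a is (T_ab + T_ac - T_bc) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .variant_io import MISSING, GenomeMask, HaplotypeSet, PopMap, Window


@dataclass
class FstComponents:
    """Per-site Weir-Cockerham variance components.

    a: among populations; b: among individuals within populations;
    c: within individuals (heterozygosity).
    """

    a: float
    b: float
    c: float


@dataclass
class FstWindowResult:
    fst_raw: float  # ratio of sums; NaN when no informative site
    fst_clamped: float  # max(raw, 0); NaN propagates
    n_informative: int = 0
    sum_a: float = 0.0
    sum_abc: float = 0.0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.fst_raw)


def _hap_freqs(haps: HaplotypeSet, rows: np.ndarray, idx: np.ndarray):
    """(n called haplotypes, alt frequency) per site, vectorized."""
    sub = haps.matrix[np.ix_(rows, idx)]
    called = sub != MISSING
    n = called.sum(axis=0)
    alt = np.where(sub == 1, 1, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return n, p


def window_pi(
    haps: HaplotypeSet,
    popmap: PopMap,
    population: str,
    window: Window,
    callable_mask: GenomeMask | None = None,
) -> float:
    """Per-bp nucleotide diversity of one population in a window.

    Sums the unbiased per-site estimator 2*p*(1-p)*n/(n-1) over window
    SNPs (n = called haplotypes at the site; sites with n < 2 skipped)
    and divides by the window length, or by callable bp when a mask is
    supplied. Equals the mean pairwise haplotype difference per bp.
    """
    rows = haps.population_rows(popmap, population)
    if len(rows) < 2:
        raise ValueError(f"population {population!r} needs >= 2 haplotypes")
    idx = haps.window_site_indices(window)
    n, p = _hap_freqs(haps, rows, idx)
    ok = n >= 2
    nn = n[ok].astype(float)
    pp = p[ok]
    total = float((2.0 * pp * (1.0 - pp) * nn / (nn - 1.0)).sum())
    denom = (
        callable_mask.overlap_bp(window.chrom, window.start, window.end)
        if callable_mask is not None
        else window.length
    )
    if denom <= 0:
        raise ValueError("zero accessible length in window")
    return total / denom


def dxy(
    haps: HaplotypeSet,
    popmap: PopMap,
    pop_a,
    pop_b,
    region: tuple,
    callable_mask: GenomeMask | None = None,
) -> float:
    """Mean between-population pairwise divergence per bp over a region.

    ``region`` is (chrom, start, end) 0-based half-open; per site the
    contribution is pA*(1-pB) + pB*(1-pA). Population arguments may be a
    label or a tuple of labels (pooled).
    """
    chrom, start, end = region
    rows_a = haps.population_rows(popmap, *_as_tuple(pop_a))
    rows_b = haps.population_rows(popmap, *_as_tuple(pop_b))
    if len(rows_a) == 0 or len(rows_b) == 0:
        raise ValueError("both populations need >= 1 haplotype")
    idx = haps.window_site_indices(Window(chrom, start, end))
    na, pa = _hap_freqs(haps, rows_a, idx)
    nb, pb = _hap_freqs(haps, rows_b, idx)
    ok = (na > 0) & (nb > 0)
    total = float((pa[ok] * (1.0 - pb[ok]) + pb[ok] * (1.0 - pa[ok])).sum())
    denom = (
        callable_mask.overlap_bp(chrom, start, end) if callable_mask is not None else end - start
    )
    if denom <= 0:
        raise ValueError("zero accessible length in region")
    return total / denom


def wc_site_components(
    n_i: np.ndarray, p_i: np.ndarray, h_i: np.ndarray
) -> FstComponents:
    """Two-allele Weir & Cockerham (1984) variance components for one site.

    n_i: diploid sample sizes per population; p_i: alt-allele frequency
    per population; h_i: observed heterozygote frequency per population.
    """
    n_i = np.asarray(n_i, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    h_i = np.asarray(h_i, dtype=float)
    r = len(n_i)
    nbar = n_i.mean()
    if nbar <= 1 or r < 2:
        return FstComponents(0.0, 0.0, 0.0)
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    if nc <= 0:
        return FstComponents(0.0, 0.0, 0.0)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return FstComponents(a, b, c)


def fst_weir_cockerham_window(
    haps: HaplotypeSet,
    popmap: PopMap,
    pop_a,
    pop_b,
    window: Window,
) -> FstWindowResult:
    """Window Fst between two populations, ratio-of-sums over sites.

    Sites where a + b + c == 0 (uninformative) are excluded; windows with
    no informative site get NaN and are excluded from quantile ranking.
    """
    rows_a = haps.population_rows(popmap, *_as_tuple(pop_a))
    rows_b = haps.population_rows(popmap, *_as_tuple(pop_b))
    idx = haps.window_site_indices(window)
    n_i = np.empty((2, len(idx)))
    p_i = np.empty((2, len(idx)))
    h_i = np.empty((2, len(idx)))
    for k, rows in enumerate((rows_a, rows_b)):
        g0 = haps.matrix[np.ix_(rows[0::2], idx)]
        g1 = haps.matrix[np.ix_(rows[1::2], idx)]
        called = (g0 != MISSING) & (g1 != MISSING)
        n = called.sum(axis=0)
        dose = np.where(called, g0 + g1, 0).sum(axis=0)
        het = np.where(called, g0 != g1, False).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n_i[k] = n
            p_i[k] = np.where(n > 0, dose / np.maximum(2 * n, 1), np.nan)
            h_i[k] = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    usable = (n_i > 0).all(axis=0)
    a, abc = _wc_components_vector(n_i[:, usable], p_i[:, usable], h_i[:, usable])
    informative = abc != 0.0
    n_inf = int(informative.sum())
    sum_a = float(a[informative].sum())
    sum_abc = float(abc[informative].sum())
    if n_inf == 0 or sum_abc == 0.0:
        return FstWindowResult(math.nan, math.nan)
    raw = sum_a / sum_abc
    return FstWindowResult(raw, max(raw, 0.0), n_inf, sum_a, sum_abc)


def _wc_components_vector(n_i, p_i, h_i):
    """Vectorized two-population W&C components; returns (a, a+b+c)."""
    r = 2.0
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
    bad = (nbar <= 1) | (nc <= 0)
    a = np.where(bad, 0.0, a)
    abc = np.where(bad, 0.0, a + b + c)
    return a, abc


def fst_to_t(fst: float, fst_cap: float = 0.995) -> float:
    """Log transform T = -ln(1 - Fst), with Fst capped to avoid infinities."""
    if math.isnan(fst):
        return math.nan
    fst = min(max(fst, 0.0), fst_cap)
    return -math.log(1.0 - fst)


def pbs_from_fst(
    fst_ab: float, fst_ac: float, fst_bc: float, fst_cap: float = 0.995
) -> tuple:
    """Population branch statistics for the three branches a, b, c.

    pbs_a = (T_ab + T_ac - T_bc) / 2 with T = -ln(1 - Fst); cyclic for
    b and c. Inputs are clamped to [0, fst_cap] first.
    """
    t_ab = fst_to_t(fst_ab, fst_cap)
    t_ac = fst_to_t(fst_ac, fst_cap)
    t_bc = fst_to_t(fst_bc, fst_cap)
    pbs_a = (t_ab + t_ac - t_bc) / 2.0
    pbs_b = (t_ab + t_bc - t_ac) / 2.0
    pbs_c = (t_ac + t_bc - t_ab) / 2.0
    return pbs_a, pbs_b, pbs_c


def empirical_quantile_threshold(values, tail: str, q: float = 0.01) -> float:
    """Nearest-rank empirical quantile threshold.

    ``tail='upper'`` returns the ceil(q*N)-th largest finite value (so at
    least a fraction q of values are >= the threshold); ``'lower'`` is the
    mirror image. NaNs are excluded.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to rank")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    k = max(1, math.ceil(q * v.size))
    v = np.sort(v)
    return float(v[-k]) if tail == "upper" else float(v[k - 1])


def three_population_window_table(
    haps: HaplotypeSet,
    popmap: PopMap,
    windows: list,
    focal,
    sister,
    outgroup,
    fst_cap: float = 0.995,
    min_snps: int = 10,
    callable_mask: GenomeMask | None = None,
):
    """Per-window table of pi, pairwise Fst/T, and PBS for a 3-pop contrast.

    ``focal``/``sister``/``outgroup`` may be labels or tuples of labels
    (pooled). Windows with fewer than ``min_snps`` informative SNPs have
    NaN Fst/PBS so they drop out of quantile ranking. Partial trailing
    windows are likewise excluded from ranking by the caller.
    """
    import pandas as pd

    rows = []
    for w in windows:
        idx = haps.window_site_indices(w)
        pi_focal = _pooled_pi(haps, popmap, _as_tuple(focal), w, callable_mask)
        pi_sister = _pooled_pi(haps, popmap, _as_tuple(sister), w, callable_mask)
        res_fs = fst_weir_cockerham_window(haps, popmap, focal, sister, w)
        res_fo = fst_weir_cockerham_window(haps, popmap, focal, outgroup, w)
        res_so = fst_weir_cockerham_window(haps, popmap, sister, outgroup, w)
        enough = len(idx) >= min_snps and not w.is_partial
        if enough and res_fs.defined and res_fo.defined and res_so.defined:
            pbs_f, pbs_s, pbs_o = pbs_from_fst(
                res_fs.fst_clamped, res_fo.fst_clamped, res_so.fst_clamped, fst_cap
            )
        else:
            pbs_f = pbs_s = pbs_o = math.nan
        pi_ratio = pi_focal / pi_sister if pi_sister > 0 else math.nan
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": len(idx),
                "pi_focal": pi_focal,
                "pi_sister": pi_sister,
                "pi_ratio": pi_ratio,
                "fst_focal_sister": res_fs.fst_clamped,
                "fst_focal_out": res_fo.fst_clamped,
                "fst_sister_out": res_so.fst_clamped,
                "pbs_focal": pbs_f,
                "pbs_sister": pbs_s,
                "pbs_out": pbs_o,
            }
        )
    return pd.DataFrame(rows)


def _pooled_pi(haps, popmap, pops, window, callable_mask):
    # reuse window_pi through a pooled pseudo-population
    pooled = PopMap({s: "_pool" for p in pops for s in popmap.samples_in(p)})
    return window_pi(haps, pooled, "_pool", window, callable_mask)


def _as_tuple(pop):
    return tuple(pop) if isinstance(pop, (tuple, list)) else (pop,)
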