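"""EHH, iHH and cross-population XP-EHH with genome-wide normalization.

EHH here is the pooled, allele-agnostic variant used by XP-EHH: the
probability that two randomly drawn haplotypes of a population are
identical over all SNPs from the core (exclusive) out to the evaluation
point (EHH = 1 at the core by convention). iHH is the trapezoidal
integral of EHH over genetic distance, both directions from the core,
truncated where the POOLED two-population EHH decays below a cutoff.
The raw score ln(iHH_A / iHH_B) is z-normalized over all scored sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import MISSING, HaplotypeSet, PopMap


@dataclass
class EHHCurve:
    core_index: int
    direction: str  # "left" | "right"
    site_indices: np.ndarray  # column indices, core first
    offsets_bp: np.ndarray  # |distance| from core, starts at 0
    offsets_cm: np.ndarray
    ehh: np.ndarray  # starts at 1.0


@dataclass
class XPEHHScore:
    site: int
    chrom: str
    pos: int
    ihh_a: float
    ihh_b: float
    raw: float
    normalized: float = math.nan


def _ehh_vector(sub: np.ndarray) -> np.ndarray:
    """Identical-pair fractions over growing prefixes of walk columns.

    ``sub`` is (n_haplotypes x m) holding the walk columns AFTER the
    core, in outward order; returns EHH at prefix lengths 1..m. Sorts
    haplotypes lexicographically once, finds the first-difference
    column of each adjacent pair, and accumulates run splits in
    activation order (piecewise-constant pair counts).
    """
    import bisect

    n, m = sub.shape
    if m == 0:
        return np.empty(0)
    if n < 2:
        return np.zeros(m)
    order = np.lexsort(sub.T[::-1])
    s = sub[order]
    neq = s[1:] != s[:-1]
    any_neq = neq.any(axis=1)
    # first column where adjacent sorted haplotypes differ (m = never)
    d = np.where(any_neq, neq.argmax(axis=1), m)
    total_pairs = n * (n - 1) // 2
    delimiters = [0, n]
    pairs_seq = [total_pairs]
    pairs = total_pairs
    for i in np.argsort(d, kind="stable"):
        if d[i] == m:
            break
        p = int(i) + 1
        j = bisect.bisect_left(delimiters, p)
        a, b = delimiters[j - 1], delimiters[j]
        pairs -= (p - a) * (b - p)
        bisect.insort(delimiters, p)
        pairs_seq.append(pairs)
    pairs_seq = np.asarray(pairs_seq, dtype=float)
    # EHH at prefix k uses boundaries with d < k
    n_active = np.searchsorted(np.sort(d), np.arange(1, m + 1), side="left")
    return pairs_seq[n_active] / total_pairs


def _ehh_along(matrix: np.ndarray, cols: list) -> np.ndarray:
    """EHH values along a fixed column walk (first entry is the core).

    Returns an array the same length as ``cols``; element 0 is 1.0 and
    element k is the identical-pair fraction over columns 1..k.
    Haplotypes with a missing allele anywhere in the walk are dropped.
    """
    sub = matrix[:, cols]
    keep = ~(sub == MISSING).any(axis=1)
    out = np.empty(len(cols))
    out[0] = 1.0
    out[1:] = _ehh_vector(sub[keep][:, 1:])
    return out


def _column_walk(
    positions: np.ndarray,
    core: int,
    direction: str,
    max_extend_bp: float,
    bounds: tuple | None,
) -> np.ndarray:
    """Column indices from the core outward, bounded by distance/interval.

    ``positions`` must be strictly increasing; the walk starts at the
    core and extends until the distance cap or the bounds interval ends.
    """
    core_pos = int(positions[core])
    if direction == "right":
        limit = core_pos + max_extend_bp
        if bounds is not None:
            limit = min(limit, bounds[1])  # pos-1 < bounds[1]
        hi = int(np.searchsorted(positions, limit, side="right"))
        return np.arange(core, hi)
    limit = core_pos - max_extend_bp
    if bounds is not None:
        limit = max(limit, bounds[0] + 1)  # pos-1 >= bounds[0]
    lo = int(np.searchsorted(positions, limit, side="left"))
    return np.arange(core, lo - 1, -1)


def ehh_curve(
    hap_matrix: np.ndarray,
    positions: np.ndarray,
    core_site: int,
    direction: str,
    cm_per_mb: float = 1.0,
    max_extend_bp: float = 1_000_000,
    bounds: tuple | None = None,
) -> EHHCurve:
    """EHH decay curve in one direction from a core SNP.

    ``hap_matrix`` is (n_haplotypes x n_sites) for one population on one
    chromosome; ``positions`` are the matching 1-based coordinates.
    ``bounds`` optionally restricts the scan to a half-open bp interval
    (e.g. a simulation window).
    """
    if hap_matrix.shape[0] < 2:
        raise ValueError("need >= 2 haplotypes for EHH")
    cols = _column_walk(positions, core_site, direction, max_extend_bp, bounds)
    ehh = _ehh_along(hap_matrix, cols)
    offsets_bp = np.abs(positions[cols].astype(float) - float(positions[core_site]))
    return EHHCurve(
        core_index=core_site,
        direction=direction,
        site_indices=np.asarray(cols),
        offsets_bp=offsets_bp,
        offsets_cm=offsets_bp * cm_per_mb / 1e6,
        ehh=ehh,
    )


class _PooledEHHWalker:
    """Incremental pooled-EHH walk with early stop at the decay cutoff."""

    def __init__(self, matrix: np.ndarray, cols: np.ndarray, cutoff: float):
        self.matrix = matrix
        self.cols = np.asarray(cols)
        self.cutoff = cutoff

    def truncated(self) -> int:
        """Number of walk columns kept (core included), pooled EHH >= cutoff.

        Chunked evaluation: EHH usually decays within a few dozen SNPs,
        so growing prefixes are evaluated instead of the full walk.
        """
        m = len(self.cols) - 1
        if m <= 0:
            return 1
        chunk = 64
        while True:
            sub = self.matrix[:, self.cols[: 1 + min(chunk, m)]]
            keep = ~(sub == MISSING).any(axis=1)
            if keep.sum() < 2:
                return 1
            ehh = _ehh_vector(sub[keep][:, 1:])
            below = np.flatnonzero(ehh < self.cutoff)
            if len(below) or chunk >= m:
                break
            chunk *= 4
        stop = int(below[0]) if len(below) else len(ehh)
        return stop + 1


def _xpehh_at_core(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    mat_pooled: np.ndarray,
    positions: np.ndarray,
    core: int,
    decay_cutoff: float,
    max_extend_bp: float,
    cm_per_mb: float,
    bounds: tuple | None,
) -> tuple | None:
    """(iHH_A, iHH_B) at one core, or None when either integral is zero."""
    ihh_a = ihh_b = 0.0
    for direction in ("left", "right"):
        cols = _column_walk(positions, core, direction, max_extend_bp, bounds)
        n_kept = _PooledEHHWalker(mat_pooled, cols, decay_cutoff).truncated()
        if n_kept < 2:
            continue
        walk = cols[:n_kept]
        x = np.abs(positions[walk].astype(float) - float(positions[core])) * cm_per_mb / 1e6
        ihh_a += float(np.trapezoid(_ehh_along(mat_a, walk), x))
        ihh_b += float(np.trapezoid(_ehh_along(mat_b, walk), x))
    if ihh_a <= 0.0 or ihh_b <= 0.0:
        return None
    return ihh_a, ihh_b


def unstandardized_xpehh(
    haps: HaplotypeSet,
    popmap: PopMap,
    pop_a,
    pop_b,
    core_site: int,
    decay_cutoff: float = 0.05,
    max_extend_bp: float = 1_000_000,
    cm_per_mb: float = 1.0,
    maf_min: float = 0.05,
    bounds: tuple | None = None,
) -> XPEHHScore | None:
    """Raw XP-EHH = ln(iHH_A / iHH_B) at one core SNP; None when skipped.

    Skips cores with pooled minor-allele frequency below ``maf_min`` or
    with a zero iHH in either population.
    """
    rows_a = haps.population_rows(popmap, *_as_tuple(pop_a))
    rows_b = haps.population_rows(popmap, *_as_tuple(pop_b))
    rows_all = np.concatenate([rows_a, rows_b])
    chrom = haps.chroms[core_site]
    on_chrom = np.flatnonzero(haps.chroms == chrom)
    local_core = int(np.searchsorted(haps.positions[on_chrom], haps.positions[core_site]))
    positions = haps.positions[on_chrom]

    col = haps.matrix[rows_all, core_site]
    called = col != MISSING
    if called.sum() < 2:
        return None
    p = float(col[called].sum()) / called.sum()
    if min(p, 1 - p) < maf_min:
        return None

    mat_a = haps.matrix[np.ix_(rows_a, on_chrom)]
    mat_b = haps.matrix[np.ix_(rows_b, on_chrom)]
    mat_p = haps.matrix[np.ix_(rows_all, on_chrom)]
    res = _xpehh_at_core(
        mat_a, mat_b, mat_p, positions, local_core, decay_cutoff, max_extend_bp,
        cm_per_mb, bounds,
    )
    if res is None:
        return None
    ihh_a, ihh_b = res
    return XPEHHScore(
        site=core_site,
        chrom=str(chrom),
        pos=int(haps.positions[core_site]),
        ihh_a=ihh_a,
        ihh_b=ihh_b,
        raw=math.log(ihh_a / ihh_b),
    )


def xpehh_scan(
    haps: HaplotypeSet,
    popmap: PopMap,
    pop_a,
    pop_b,
    windows: list | None = None,
    decay_cutoff: float = 0.05,
    max_extend_bp: float = 1_000_000,
    cm_per_mb: float = 1.0,
    maf_min: float = 0.05,
    restrict_to_windows: bool = True,
) -> pd.DataFrame:
    """Raw XP-EHH at every eligible SNP.

    When ``windows`` are given and ``restrict_to_windows`` is set, the
    EHH extension is truncated at window boundaries — appropriate for
    cohorts whose windows were simulated without inter-window linkage.
    """
    rows_a = haps.population_rows(popmap, *_as_tuple(pop_a))
    rows_b = haps.population_rows(popmap, *_as_tuple(pop_b))
    rows_all = np.concatenate([rows_a, rows_b])

    if windows is not None:
        blocks = [(w, haps.window_site_indices(w)) for w in windows]
    else:
        blocks = []
        for chrom in dict.fromkeys(haps.chroms):
            blocks.append((None, np.flatnonzero(haps.chroms == chrom)))

    records = []
    for w, sites in blocks:
        if len(sites) == 0:
            continue
        bounds = (w.start, w.end) if (w is not None and restrict_to_windows) else None
        scan_cols = sites  # windows restrict linkage to the block itself
        mat_a = haps.matrix[np.ix_(rows_a, scan_cols)]
        mat_b = haps.matrix[np.ix_(rows_b, scan_cols)]
        mat_p = haps.matrix[np.ix_(rows_all, scan_cols)]
        positions = haps.positions[scan_cols]
        # pooled alt-allele frequencies for the MAF screen
        called = mat_p != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(
                called.sum(axis=0) > 0,
                np.where(mat_p == 1, 1, 0).sum(axis=0) / np.maximum(called.sum(axis=0), 1),
                np.nan,
            )
        eligible = np.flatnonzero(
            (called.sum(axis=0) >= 2) & (np.minimum(p, 1 - p) >= maf_min)
        )
        for local in eligible:
            res = _xpehh_at_core(
                mat_a, mat_b, mat_p, positions, int(local), decay_cutoff,
                max_extend_bp, cm_per_mb, bounds,
            )
            if res is None:
                continue
            ihh_a, ihh_b = res
            records.append(
                {
                    "site": int(scan_cols[local]),
                    "chrom": str(haps.chroms[scan_cols[local]]),
                    "pos": int(positions[local]),
                    "ihh_a": ihh_a,
                    "ihh_b": ihh_b,
                    "raw": math.log(ihh_a / ihh_b),
                }
            )
    return pd.DataFrame(records, columns=["site", "chrom", "pos", "ihh_a", "ihh_b", "raw"])


def normalize_and_window(raw_scores: pd.DataFrame, windows: list) -> pd.DataFrame:
    """z-normalize raw scores genome-wide and average per window.

    Normalization uses the population (n) standard deviation. Adds a
    ``norm`` column to ``raw_scores`` in place and returns a per-window
    frame with mean normalized XP-EHH (NaN for windows without scores).
    """
    if len(raw_scores) < 2:
        raise ValueError("need >= 2 scored sites for normalization")
    raw = raw_scores["raw"].to_numpy(dtype=float)
    sd = float(np.std(raw))
    if sd == 0.0:
        raise ValueError("zero standard deviation of raw XP-EHH scores")
    raw_scores["norm"] = (raw - raw.mean()) / sd
    rows = []
    for w in windows:
        in_w = (
            (raw_scores["chrom"] == w.chrom)
            & (raw_scores["pos"] - 1 >= w.start)
            & (raw_scores["pos"] - 1 < w.end)
        )
        vals = raw_scores.loc[in_w, "norm"]
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_scored": int(in_w.sum()),
                "xpehh": float(vals.mean()) if len(vals) else math.nan,
            }
        )
    return pd.DataFrame(rows)


def _as_tuple(pop):
    return tuple(pop) if isinstance(pop, (tuple, list)) else (pop,)
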