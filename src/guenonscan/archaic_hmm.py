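"""Reference-free archaic-introgression HMM on binned private-variant density.

A two-state (archaic / non-archaic) hidden Markov model is trained per
focal individual on counts of variants private to that individual
relative to an outgroup panel, in fixed genomic bins (default 1 kb).
Emissions are Poisson with mean lambda_state * callable_frac * rate_weight,
where rate_weight is a local background mutation-rate multiplier derived
from outgroup variant density in a surrounding window (default 100 kb),
normalized to a genome-wide mean of 1. Training is Baum-Welch EM with
scaled forward/backward recursions and deterministic multi-restart
initialization; decoding thresholds the posterior probability of the
archaic state (default 0.98) into segments.

The emission-rate readout t = lambda / (mu * bin_bp) is a deliberately
rough constant-rate divergence-time estimate: it ignores gene flow and
population-size change.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .variant_io import MISSING, GenomeMask, HaplotypeSet, PopMap

RATE_WEIGHT_FLOOR = 0.05  # multiplicative floor on local rate weights


@dataclass
class ObservationTrack:
    """Binned private-variant observations for one focal individual."""

    individual: str
    chroms: np.ndarray  # per-bin contig (object)
    starts: np.ndarray  # per-bin 0-based start (int64)
    counts: np.ndarray  # private derived-allele copies per bin (int64)
    callable_frac: np.ndarray  # fraction of bin covered by the callable mask
    rate_weight: np.ndarray  # local mutation-rate multiplier (genome mean 1)
    bin_bp: int = 1000

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def usable(self, min_callable: float = 0.5) -> np.ndarray:
        return self.callable_frac >= min_callable


@dataclass
class HMMParams:
    """Two-state HMM parameters; state 0 = archaic, state 1 = non-archaic."""

    start: np.ndarray  # shape (2,)
    trans: np.ndarray  # shape (2, 2), rows sum to 1
    lam: np.ndarray  # expected private variants per fully-callable weight-1 bin
    converged: bool = True

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)

    @property
    def lam_archaic(self) -> float:
        return float(self.lam[0])

    @property
    def lam_nonarchaic(self) -> float:
        return float(self.lam[1])


@dataclass
class Segment:
    individual: str
    chrom: str
    start: int
    end: int
    mean_pp: float

    @property
    def length_bp(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# observation building
# ---------------------------------------------------------------------------


def build_observations(
    haps: HaplotypeSet,
    popmap: PopMap,
    focal_sample: str,
    outgroup_pops,
    callable_mask: GenomeMask,
    bin_bp: int = 1000,
    rate_window_bp: int = 100_000,
) -> ObservationTrack:
    """Binned counts of focal-private allele copies plus local rate weights.

    An allele copy carried by the focal individual is private when the
    outgroup panel (all haplotypes of ``outgroup_pops``) carries zero
    copies of that allele at the site. The rate weight of a bin is the
    outgroup variant density of its enclosing ``rate_window_bp`` window
    divided by the genome-wide mean density, floored at a small epsilon.
    """
    if not callable_mask.intervals:
        raise ValueError("callable mask is empty")
    out_rows = haps.population_rows(popmap, *_as_tuple(outgroup_pops))
    if len(out_rows) < 2:
        raise ValueError("outgroup panel needs >= 2 haplotypes")
    f0, f1 = haps.sample_rows(focal_sample)

    contig_lengths = {
        chrom: int(iv[:, 1].max()) for chrom, iv in callable_mask.intervals.items()
    }

    bins: list = []
    for chrom in contig_lengths:
        n_bins = math.ceil(contig_lengths[chrom] / bin_bp)
        for b in range(n_bins):
            bins.append((chrom, b * bin_bp))
    bin_index = {key: i for i, key in enumerate(bins)}
    counts = np.zeros(len(bins), dtype=np.int64)
    out_variant_sites: dict = {}  # (chrom, rate-window index) -> count

    out_mat = haps.matrix[out_rows, :]
    for j in range(haps.n_sites):
        chrom = haps.chroms[j]
        pos0 = int(haps.positions[j]) - 1
        out_col = out_mat[:, j]
        out_called = out_col != MISSING
        # outgroup variant density track (any alt allele in the panel)
        if out_called.any() and out_col[out_called].sum() > 0:
            wkey = (chrom, pos0 // rate_window_bp)
            out_variant_sites[wkey] = out_variant_sites.get(wkey, 0) + 1
        key = (chrom, (pos0 // bin_bp) * bin_bp)
        if key not in bin_index:
            continue
        n_out = int(out_called.sum())
        if n_out == 0:
            continue
        out_has = {int(a) for a in out_col[out_called]}
        for allele in (haps.matrix[f0, j], haps.matrix[f1, j]):
            if allele != MISSING and int(allele) not in out_has:
                counts[bin_index[key]] += 1

    chroms = np.array([b[0] for b in bins], dtype=object)
    starts = np.array([b[1] for b in bins], dtype=np.int64)
    cfrac = np.array(
        [
            callable_mask.overlap_bp(c, s, min(s + bin_bp, contig_lengths[c])) / bin_bp
            for c, s in bins
        ]
    )

    win_counts = np.array(
        [out_variant_sites.get((c, s // rate_window_bp), 0) for c, s in bins], dtype=float
    )
    n_rate_windows = sum(
        math.ceil(length / rate_window_bp) for length in contig_lengths.values()
    )
    mean_density = (
        sum(out_variant_sites.values()) / n_rate_windows if n_rate_windows else 0.0
    )
    if mean_density > 0:
        weights = np.maximum(win_counts / mean_density, RATE_WEIGHT_FLOOR)
    else:
        weights = np.ones(len(bins))
    return ObservationTrack(
        individual=focal_sample,
        chroms=chroms,
        starts=starts,
        counts=counts,
        callable_frac=cfrac,
        rate_weight=weights,
        bin_bp=bin_bp,
    )


# ---------------------------------------------------------------------------
# Baum-Welch training
# ---------------------------------------------------------------------------


def _chrom_slices(track: ObservationTrack) -> list:
    slices = []
    start = 0
    for i in range(1, track.n_bins + 1):
        if i == track.n_bins or track.chroms[i] != track.chroms[start]:
            slices.append(slice(start, i))
            start = i
    return slices


def _log_emissions(track: ObservationTrack, lam: np.ndarray, min_callable: float) -> np.ndarray:
    """(2, T) log emission probabilities; masked bins emit log 1 = 0."""
    exposure = track.callable_frac * track.rate_weight
    usable = track.usable(min_callable)
    loge = np.zeros((2, track.n_bins))
    for s in range(2):
        mu = np.maximum(lam[s] * exposure, 1e-300)
        loge[s] = poisson.logpmf(track.counts, mu)
    loge[:, ~usable] = 0.0
    return loge


def _forward_backward(loge: np.ndarray, start: np.ndarray, trans: np.ndarray):
    """Scaled forward/backward for one chromosome.

    Returns (log_likelihood, gamma (T,2), xi_sum (2,2)).
    """
    T = loge.shape[1]
    e = np.exp(loge - loge.max(axis=0, keepdims=True))  # per-bin rescaled emissions
    log_corr = loge.max(axis=0)  # add back per-bin max
    alpha = np.zeros((T, 2))
    scale = np.zeros(T)
    a = start * e[:, 0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * e[:, t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    loglik = float(np.log(scale).sum() + log_corr.sum())

    beta = np.zeros((T, 2))
    beta[-1] = 1.0
    xi_sum = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        beta[t] = (trans @ (e[:, t + 1] * beta[t + 1])) / scale[t + 1]
        xi = trans * np.outer(alpha[t], e[:, t + 1] * beta[t + 1]) / scale[t + 1]
        xi_sum += xi
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return loglik, gamma, xi_sum


def _baum_welch(
    track: ObservationTrack,
    init: HMMParams,
    tol: float,
    max_iter: int,
    min_callable: float,
):
    start = init.start.copy()
    trans = init.trans.copy()
    lam = init.lam.copy()
    slices = _chrom_slices(track)
    exposure = track.callable_frac * track.rate_weight
    usable = track.usable(min_callable)
    prev_ll = -math.inf
    converged = False
    history = []
    for _ in range(max_iter):
        loge = _log_emissions(track, lam, min_callable)
        total_ll = 0.0
        gamma_all = np.zeros((track.n_bins, 2))
        xi_total = np.zeros((2, 2))
        start_acc = np.zeros(2)
        for sl in slices:
            ll, gamma, xi = _forward_backward(loge[:, sl], start, trans)
            total_ll += ll
            gamma_all[sl] = gamma
            xi_total += xi
            start_acc += gamma[0]
        history.append(total_ll)
        # M step
        start = start_acc / start_acc.sum()
        trans = xi_total / xi_total.sum(axis=1, keepdims=True)
        g = gamma_all[usable]
        c = track.counts[usable]
        x = exposure[usable]
        for s in range(2):
            denom = float((g[:, s] * x).sum())
            lam[s] = float((g[:, s] * c).sum()) / denom if denom > 0 else lam[s]
        start = np.clip(start, 1e-12, None)
        start /= start.sum()
        trans = np.clip(trans, 1e-12, None)
        trans /= trans.sum(axis=1, keepdims=True)
        if abs(total_ll - prev_ll) < tol:
            converged = True
            prev_ll = total_ll
            break
        prev_ll = total_ll
    params = HMMParams(start=start, trans=trans, lam=lam, converged=converged)
    return params, prev_ll, history


def _canonicalize(params: HMMParams) -> HMMParams:
    """Label-swap so state 0 (archaic) has the larger emission rate."""
    if params.lam[0] >= params.lam[1]:
        return params
    perm = [1, 0]
    return HMMParams(
        start=params.start[perm],
        trans=params.trans[np.ix_(perm, perm)],
        lam=params.lam[perm],
        converged=params.converged,
    )


def train_hmm(
    track: ObservationTrack,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 1000,
    min_callable: float = 0.5,
) -> tuple:
    """Baum-Welch training with deterministic multi-restart initialization.

    Restart k initializes the non-archaic rate at the genome-mean count
    per unit exposure and the archaic rate at 2^(k+1) times that, with a
    small seeded jitter; the best-likelihood restart is returned, label
    -swapped so lambda_archaic > lambda_nonarchaic.
    """
    usable = track.usable(min_callable)
    if int(usable.sum()) < 100:
        raise ValueError("need >= 100 usable bins to train")
    exposure = track.callable_frac * track.rate_weight
    base = float(track.counts[usable].sum()) / float(exposure[usable].sum())
    base = max(base, 1e-6)
    rng = np.random.default_rng(seed)
    best = None
    factors = [2.0**k for k in range(1, n_restarts + 1)]
    for k, fac in enumerate(factors):
        jitter = 1.0 + 0.05 * rng.standard_normal() if k > 0 else 1.0
        init = HMMParams(
            start=np.array([0.05, 0.95]),
            trans=np.array([[0.9, 0.1], [0.01, 0.99]]),
            lam=np.array([base * fac * abs(jitter), base]),
        )
        params, ll, _ = _baum_welch(track, init, tol, max_iter, min_callable)
        if best is None or ll > best[1]:
            best = (params, ll)
    params, ll = best
    if not params.converged:
        warnings.warn("Baum-Welch did not converge within max_iter", stacklevel=2)
    return _canonicalize(params), ll


def em_loglik_history(
    track: ObservationTrack,
    init: HMMParams,
    max_iter: int = 50,
    min_callable: float = 0.5,
) -> list:
    """Log-likelihood trace of a single EM run (monotone non-decreasing)."""
    _, _, history = _baum_welch(track, init, tol=0.0, max_iter=max_iter, min_callable=min_callable)
    return history


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def posterior_decode(
    track: ObservationTrack, params: HMMParams, min_callable: float = 0.5
) -> np.ndarray:
    """(T, 2) posterior state probabilities from forward-backward."""
    loge = _log_emissions(track, params.lam, min_callable)
    post = np.zeros((track.n_bins, 2))
    for sl in _chrom_slices(track):
        _, gamma, _ = _forward_backward(loge[:, sl], params.start, params.trans)
        post[sl] = gamma
    return post


def decode_segments(
    track: ObservationTrack,
    params: HMMParams,
    pp_cutoff: float = 0.98,
    min_len_bp: int = 0,
    min_callable: float = 0.5,
) -> tuple:
    """Call archaic segments as maximal runs of high-posterior bins.

    Returns (segments, posterior). A segment is a maximal run of
    consecutive usable bins with P(archaic) >= ``pp_cutoff``; segments
    shorter than ``min_len_bp`` are dropped.
    """
    post = posterior_decode(track, params, min_callable)
    usable = track.usable(min_callable)
    hot = (post[:, 0] >= pp_cutoff) & usable
    segments = []
    i = 0
    T = track.n_bins
    while i < T:
        if not hot[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < T
            and hot[j + 1]
            and track.chroms[j + 1] == track.chroms[i]
            and track.starts[j + 1] == track.starts[j] + track.bin_bp
        ):
            j += 1
        start = int(track.starts[i])
        end = int(track.starts[j]) + track.bin_bp
        if end - start >= min_len_bp:
            segments.append(
                Segment(
                    individual=track.individual,
                    chrom=str(track.chroms[i]),
                    start=start,
                    end=end,
                    mean_pp=float(post[i : j + 1, 0].mean()),
                )
            )
        i = j + 1
    return segments, post


def shared_segments(segment_lists: dict) -> tuple:
    """Genomic intersection of all individuals' segment sets.

    ``segment_lists`` maps individual -> list of Segments (or
    (chrom, start, end) tuples). Returns (intervals, total_bp).
    """
    if len(segment_lists) < 2:
        raise ValueError("need >= 2 individuals to intersect")
    current = None
    for segs in segment_lists.values():
        ivs = sorted(
            (s.chrom, s.start, s.end) if isinstance(s, Segment) else tuple(s) for s in segs
        )
        current = ivs if current is None else _intersect(current, ivs)
    total = sum(e - s for _, s, e in current)
    return current, int(total)


def _intersect(a: list, b: list) -> list:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        ca, sa, ea = a[i]
        cb, sb, eb = b[j]
        if ca == cb:
            lo, hi = max(sa, sb), min(ea, eb)
            if lo < hi:
                out.append((ca, lo, hi))
            if (ea, ca) <= (eb, cb):
                i += 1
            else:
                j += 1
        elif ca < cb:
            i += 1
        else:
            j += 1
    return out


def state_divergence_time(
    params: HMMParams, mu_per_bp_year: float, bin_bp: int = 1000
) -> dict:
    """Rough per-state divergence times t = lambda / (mu * bin_bp), in years.

    A constant-rate readout that ignores gene flow and size change; both
    states are reported, neither is privileged.
    """
    if mu_per_bp_year <= 0:
        raise ValueError("mutation rate must be positive")
    return {
        "archaic": params.lam_archaic / (mu_per_bp_year * bin_bp),
        "nonarchaic": params.lam_nonarchaic / (mu_per_bp_year * bin_bp),
    }


def segments_to_bed(segments: list, path) -> None:
    """Write segments as BED with the mean posterior in the score column."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.individual}\t{s.mean_pp:.4f}\n")


def _as_tuple(pop):
    return tuple(pop) if isinstance(pop, (tuple, list)) else (pop,)
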