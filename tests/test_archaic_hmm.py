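"""Observation building, Baum-Welch training and posterior decoding."""

import math

import numpy as np
import pytest

from guenonscan.archaic_hmm import (
    HMMParams,
    ObservationTrack,
    build_observations,
    decode_segments,
    em_loglik_history,
    posterior_decode,
    shared_segments,
    state_divergence_time,
    train_hmm,
)
from guenonscan.variant_io import GenomeMask, PopMap

from conftest import make_haps


def _track(counts, chrom="c", bin_bp=1000, cfrac=None, weight=None):
    counts = np.asarray(counts, dtype=np.int64)
    T = len(counts)
    return ObservationTrack(
        individual="f",
        chroms=np.array([chrom] * T, dtype=object),
        starts=np.arange(T, dtype=np.int64) * bin_bp,
        counts=counts,
        callable_frac=np.ones(T) if cfrac is None else np.asarray(cfrac, float),
        rate_weight=np.ones(T) if weight is None else np.asarray(weight, float),
        bin_bp=bin_bp,
    )


def _simulate_counts(rng, params, T, exposure=None):
    exposure = np.ones(T) if exposure is None else exposure
    states = np.zeros(T, dtype=int)
    states[0] = rng.choice(2, p=params.start)
    for t in range(1, T):
        states[t] = rng.choice(2, p=params.trans[states[t - 1]])
    counts = rng.poisson(params.lam[states] * exposure)
    return states, counts


# --- observation building ---------------------------------------------------


def test_private_counts_zero_when_focal_matches_outgroup():
    m = np.array(
        [
            [0, 1, 0, 1],  # focal hap 0
            [1, 0, 1, 0],  # focal hap 1
            [0, 1, 0, 1],  # outgroup...
            [1, 0, 1, 0],
            [0, 0, 1, 1],
            [1, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    haps = make_haps(m, positions=[100, 600, 1100, 1600])
    pm = PopMap({"s0": "East", "s1": "WCa", "s2": "WCb"})
    mask = GenomeMask({"chr1": [(0, 2000)]})
    track = build_observations(haps, pm, "s0", ("WCa", "WCb"), mask)
    assert track.counts.sum() == 0


def test_single_private_allele_counted_in_right_bin():
    m = np.zeros((6, 3), dtype=np.int8)
    m[0, 1] = 1  # focal carries one allele absent from the panel
    haps = make_haps(m, positions=[100, 1500, 2500])
    pm = PopMap({"s0": "East", "s1": "WCa", "s2": "WCb"})
    mask = GenomeMask({"chr1": [(0, 3000)]})
    track = build_observations(haps, pm, "s0", ("WCa", "WCb"), mask)
    assert track.counts.tolist() == [0, 1, 0]
    # homozygous private allele counts two copies
    m[1, 1] = 1
    track2 = build_observations(
        make_haps(m, positions=[100, 1500, 2500]), pm, "s0", ("WCa", "WCb"), mask
    )
    assert track2.counts.tolist() == [0, 2, 0]


def test_rate_weights_match_hand_computed_densities():
    """10 bins over two 5-kb rate windows with known outgroup densities."""
    positions, cols = [], []
    # outgroup variants: 6 in window 0, 2 in window 1
    out_sites = [500, 1200, 2300, 3100, 4200, 4800, 5500, 9100]
    for p in out_sites:
        positions.append(p)
        cols.append([0, 0, 1, 0, 0, 0])  # alt allele in the panel only
    order = np.argsort(positions)
    m = np.array(cols, dtype=np.int8).T[:, order]
    haps = make_haps(m, positions=np.array(positions)[order])
    pm = PopMap({"s0": "East", "s1": "WCa", "s2": "WCb"})
    mask = GenomeMask({"chr1": [(0, 10_000)]})
    track = build_observations(
        haps, pm, "s0", ("WCa", "WCb"), mask, bin_bp=1000, rate_window_bp=5000
    )
    mean_density = (6 + 2) / 2
    np.testing.assert_allclose(track.rate_weight[:5], 6 / mean_density)
    np.testing.assert_allclose(track.rate_weight[5:], 2 / mean_density)


def test_observation_conservation(admixed_cohort):
    """Binned counts sum to the genome-wide focal-private allele count."""
    co = admixed_cohort
    focal = "East_1"
    track = build_observations(co.haps, co.popmap, focal, ("WCa", "WCb"), co.callable_mask)
    f0, f1 = co.haps.sample_rows(focal)
    out_rows = co.haps.population_rows(co.popmap, "WCa", "WCb")
    total = 0
    out = co.haps.matrix[out_rows]
    for j in range(co.haps.n_sites):
        carried = {int(co.haps.matrix[f0, j]), int(co.haps.matrix[f1, j])} - {-1}
        present = set(np.unique(out[:, j])) - {-1}
        for allele in (int(co.haps.matrix[f0, j]), int(co.haps.matrix[f1, j])):
            if allele != -1 and allele not in present:
                total += 1
    assert track.counts.sum() == total


def test_empty_mask_rejected():
    haps = make_haps(np.zeros((6, 1), dtype=np.int8))
    pm = PopMap({"s0": "East", "s1": "WCa", "s2": "WCb"})
    with pytest.raises(ValueError, match="mask"):
        build_observations(haps, pm, "s0", ("WCa", "WCb"), GenomeMask({}))


# --- training ---------------------------------------------------------------


def test_parameter_recovery_on_self_simulated_data():
    """Rates within 10% and transitions within 20% relative error."""
    rng = np.random.default_rng(5)
    true = HMMParams(
        start=np.array([0.1, 0.9]),
        trans=np.array([[0.92, 0.08], [0.004, 0.996]]),
        lam=np.array([6.0, 0.5]),
    )
    _, counts = _simulate_counts(rng, true, 50_000)
    track = _track(counts)
    params, ll = train_hmm(track, n_restarts=3, seed=0)
    assert params.lam_archaic == pytest.approx(true.lam[0], rel=0.10)
    assert params.lam_nonarchaic == pytest.approx(true.lam[1], rel=0.10)
    assert params.trans[0, 0] == pytest.approx(true.trans[0, 0], rel=0.20)
    assert params.trans[1, 1] == pytest.approx(true.trans[1, 1], rel=0.20)


def test_homogeneous_data_yields_no_segments():
    rng = np.random.default_rng(11)
    counts = rng.poisson(0.5, size=5000)
    track = _track(counts)
    params, _ = train_hmm(track, n_restarts=2, seed=1)
    segs, post = decode_segments(track, params, pp_cutoff=0.98)
    assert segs == []


def test_em_loglik_monotone():
    rng = np.random.default_rng(3)
    counts = np.concatenate([rng.poisson(0.4, 300), rng.poisson(4.0, 50),
                             rng.poisson(0.4, 300)])
    init = HMMParams(
        start=np.array([0.1, 0.9]),
        trans=np.array([[0.8, 0.2], [0.05, 0.95]]),
        lam=np.array([3.0, 0.6]),
    )
    hist = em_loglik_history(_track(counts), init, max_iter=40)
    assert all(b >= a - 1e-8 for a, b in zip(hist, hist[1:]))


def test_training_requires_enough_bins():
    with pytest.raises(ValueError, match="100"):
        train_hmm(_track(np.zeros(50)))


def test_label_ordering_archaic_has_larger_rate():
    rng = np.random.default_rng(7)
    counts = np.concatenate([rng.poisson(5.0, 500), rng.poisson(0.3, 4500)])
    params, _ = train_hmm(_track(counts), n_restarts=2, seed=0)
    assert params.lam_archaic > params.lam_nonarchaic


# --- decoding ---------------------------------------------------------------


def test_posteriors_normalize():
    rng = np.random.default_rng(9)
    counts = rng.poisson(1.0, 500)
    track = _track(counts)
    params = HMMParams(
        start=np.array([0.2, 0.8]),
        trans=np.array([[0.9, 0.1], [0.1, 0.9]]),
        lam=np.array([3.0, 0.5]),
    )
    post = posterior_decode(track, params)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


def test_cutoff_monotonicity():
    """Raising the cutoff never increases the called length, and every
    called bin at the higher cutoff is called at the lower one."""
    rng = np.random.default_rng(13)
    true = HMMParams(
        start=np.array([0.1, 0.9]),
        trans=np.array([[0.9, 0.1], [0.01, 0.99]]),
        lam=np.array([5.0, 0.4]),
    )
    _, counts = _simulate_counts(rng, true, 5000)
    track = _track(counts)
    prev_bins = None
    prev_len = math.inf
    for cutoff in (0.5, 0.8, 0.9, 0.98):
        segs, _ = decode_segments(track, true, pp_cutoff=cutoff)
        called = set()
        for s in segs:
            called.update(range(s.start, s.end, track.bin_bp))
        total = sum(s.length_bp for s in segs)
        assert total <= prev_len
        if prev_bins is not None:
            assert called <= prev_bins
        prev_bins, prev_len = called, total


def test_segment_min_length_filter():
    rng = np.random.default_rng(17)
    true = HMMParams(
        start=np.array([0.1, 0.9]),
        trans=np.array([[0.9, 0.1], [0.02, 0.98]]),
        lam=np.array([6.0, 0.3]),
    )
    _, counts = _simulate_counts(rng, true, 3000)
    track = _track(counts)
    all_segs, _ = decode_segments(track, true, pp_cutoff=0.9)
    long_segs, _ = decode_segments(track, true, pp_cutoff=0.9, min_len_bp=10_000)
    assert all(s.length_bp >= 10_000 for s in long_segs)
    assert len(long_segs) <= len(all_segs)


def test_shared_segments_interval_arithmetic():
    a = [("c", 0, 5000)]
    b = [("c", 3000, 8000)]
    ivs, total = shared_segments({"i1": a, "i2": b})
    assert ivs == [("c", 3000, 5000)] and total == 2000
    same, total_same = shared_segments({"i1": a, "i2": a})
    assert same == a and total_same == 5000
    none, total_none = shared_segments({"i1": a, "i2": [("c", 6000, 7000)]})
    assert none == [] and total_none == 0


def test_state_divergence_time_readout():
    params = HMMParams(
        start=np.array([0.1, 0.9]),
        trans=np.eye(2) * 0.98 + 0.02 * (1 - np.eye(2)),
        lam=np.array([0.1, 0.0]),
    )
    t = state_divergence_time(params, mu_per_bp_year=0.99e-9, bin_bp=1000)
    assert t["archaic"] == pytest.approx(1.01e5, rel=1e-2)
    assert t["nonarchaic"] == 0.0
    t2 = state_divergence_time(params, mu_per_bp_year=2 * 0.99e-9, bin_bp=1000)
    assert t2["archaic"] == pytest.approx(t["archaic"] / 2)
    with pytest.raises(ValueError):
        state_divergence_time(params, 0.0)


def test_called_lengths_track_truth_across_pulse_fractions():
    """Across cohorts spanning a range of pulse fractions, per-individual
    called length correlates with truth length (Spearman > 0.9), and
    individuals sharing one demography have similar totals (CV < 0.2)."""
    from dataclasses import replace

    from scipy.stats import spearmanr

    from guenonscan.synthetic_data import DemographyConfig, simulate_cohort

    truth_lengths, called_lengths = [], []
    for k, f in enumerate((0.02, 0.05, 0.08, 0.12, 0.15)):
        cfg = replace(DemographyConfig(), ghost_fraction=f)
        co = simulate_cohort(cfg, n_windows=120, window_bp=50_000, seed=500 + k)
        for focal in ("East_1", "East_2"):
            track = build_observations(
                co.haps, co.popmap, focal, ("WCa", "WCb"), co.callable_mask
            )
            params, _ = train_hmm(track, n_restarts=3, seed=k)
            segs, _ = decode_segments(track, params, pp_cutoff=0.98)
            truth_lengths.append(co.truth.tract_bp(focal))
            called_lengths.append(sum(s.length_bp for s in segs))
    rho = spearmanr(truth_lengths, called_lengths).statistic
    assert rho > 0.9


def test_same_demography_individuals_have_similar_called_totals():
    """Individuals sharing one demography have similar introgressed
    totals (coefficient of variation < 0.2). Needs a genome large
    enough (20 Mb here) that the truth totals themselves cluster."""
    from guenonscan.synthetic_data import DemographyConfig, simulate_cohort

    co = simulate_cohort(DemographyConfig(), n_windows=400, window_bp=50_000, seed=606)
    totals = []
    for focal in co.popmap.samples_in("East"):
        track = build_observations(
            co.haps, co.popmap, focal, ("WCa", "WCb"), co.callable_mask
        )
        params, _ = train_hmm(track, n_restarts=2, seed=1)
        segs, _ = decode_segments(track, params, pp_cutoff=0.98)
        totals.append(sum(s.length_bp for s in segs))
    totals = np.asarray(totals, dtype=float)
    cv = totals.std(ddof=1) / totals.mean()
    assert cv < 0.2
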