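"""Diversity, divergence, Weir-Cockerham Fst and PBS.

Oracles: pi and dxy against direct pairwise-difference enumeration;
window Fst against an independently hand-coded variance-components
evaluation; PBS against its closed form.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guenonscan.popgen_stats import (
    dxy,
    empirical_quantile_threshold,
    fst_weir_cockerham_window,
    pbs_from_fst,
    wc_site_components,
    window_pi,
)
from guenonscan.variant_io import PopMap, Window

from conftest import make_haps, random_haps


# --- independent oracles ----------------------------------------------------


def oracle_pi(matrix, length):
    """Mean pairwise haplotype difference per bp (no missing data)."""
    n = matrix.shape[0]
    total = sum(
        (matrix[i] != matrix[j]).sum() for i in range(n) for j in range(i + 1, n)
    )
    return total / (n * (n - 1) / 2) / length


def oracle_dxy(mat_a, mat_b, length):
    total = sum((a != b).sum() for a in mat_a for b in mat_b)
    return total / (len(mat_a) * len(mat_b)) / length


def oracle_wc(genos_a, genos_b):
    """Weir & Cockerham (1984) a, b, c from first principles for one site.

    genos_* are lists of (allele1, allele2) diploid genotypes.
    """
    pops = [genos_a, genos_b]
    r = 2
    n_i = np.array([len(g) for g in pops], dtype=float)
    p_i = np.array([sum(a + b for a, b in g) / (2 * len(g)) for g in pops])
    h_i = np.array([sum(a != b for a, b in g) / len(g) for g in pops])
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


# --- pi ---------------------------------------------------------------------


def test_pi_single_snp_frequency_half():
    """One SNP at p=0.5 among 10 haplotypes in 1 kb: (2*0.25*10/9)/1000."""
    m = np.zeros((10, 1), dtype=np.int8)
    m[:5, 0] = 1
    haps = make_haps(m)
    pm = PopMap({f"s{i}": "P" for i in range(5)})
    pi = window_pi(haps, pm, "P", Window("chr1", 0, 1000))
    assert pi == pytest.approx(5.556e-4, rel=1e-3)
    assert pi == pytest.approx(oracle_pi(m, 1000), abs=1e-12)


def test_pi_trivial_cases():
    m = np.zeros((4, 3), dtype=np.int8)
    haps = make_haps(m)
    pm = PopMap({"s0": "P", "s1": "P"})
    assert window_pi(haps, pm, "P", Window("chr1", 0, 100)) == 0.0
    # 2 haplotypes differing at 1 site in 100 bp -> 0.01
    m2 = np.array([[0], [1]], dtype=np.int8)
    haps2 = make_haps(m2, samples=["s0"])
    # a single diploid sample provides the two haplotypes
    assert window_pi(haps2, PopMap({"s0": "P"}), "P", Window("chr1", 0, 100)) == pytest.approx(
        0.01
    )


def test_pi_matches_pairwise_oracle_on_random_instances(rng):
    for _ in range(10):
        n_samples = int(rng.integers(2, 6))
        n_sites = int(rng.integers(1, 30))
        haps = random_haps(rng, n_samples, n_sites, length=500)
        pm = PopMap({f"s{i}": "P" for i in range(n_samples)})
        got = window_pi(haps, pm, "P", Window("chr1", 0, 500))
        assert got == pytest.approx(oracle_pi(haps.matrix, 500), abs=1e-9)


# --- dxy --------------------------------------------------------------------


def test_dxy_fixed_difference_and_identity(popmap_two):
    m = np.zeros((8, 1), dtype=np.int8)
    m[4:, 0] = 1  # pop B fixed alt
    haps = make_haps(m)
    pm = PopMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
    assert dxy(haps, pm, "A", "B", ("chr1", 0, 100)) == pytest.approx(0.01)
    m[:, 0] = 1
    haps2 = make_haps(m)
    assert dxy(haps2, pm, "A", "B", ("chr1", 0, 100)) == 0.0


def test_dxy_equals_mean_interpopulation_pairwise_difference(rng):
    for _ in range(10):
        haps = random_haps(rng, 4, 20, length=1000)
        pm = PopMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        got = dxy(haps, pm, "A", "B", ("chr1", 0, 1000))
        expect = oracle_dxy(haps.matrix[:4], haps.matrix[4:], 1000)
        assert got == pytest.approx(expect, abs=1e-9)
        assert got == pytest.approx(dxy(haps, pm, "B", "A", ("chr1", 0, 1000)), abs=1e-12)
        assert got >= 0.0


def test_dxy_mixed_frequencies_against_enumeration():
    """p_A=0.5, p_B=0.25 at one site equals the A-x-B pair average."""
    mat = np.array([[0], [1], [0], [0]] + [[1], [0], [0], [0]], dtype=np.int8)
    # pop A: rows 0-3 (p=0.25)... build explicitly: A has 4 haps p=0.5
    m = np.array([[1], [0], [1], [0], [1], [0], [0], [0]], dtype=np.int8)
    haps = make_haps(m)
    pm = PopMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
    got = dxy(haps, pm, "A", "B", ("chr1", 0, 1000))
    assert got == pytest.approx(oracle_dxy(m[:4], m[4:], 1000), abs=1e-12)


# --- Fst --------------------------------------------------------------------


def test_fst_fixed_difference_is_one():
    m = np.zeros((20, 5), dtype=np.int8)
    m[10:, :] = 1
    haps = make_haps(m)
    pm = PopMap({f"s{i}": ("A" if i < 5 else "B") for i in range(10)})
    res = fst_weir_cockerham_window(haps, pm, "A", "B", Window("chr1", 0, 100))
    assert res.fst_raw == pytest.approx(1.0)


def test_fst_identical_populations_clamped_to_zero(rng):
    base = rng.integers(0, 2, size=(6, 12)).astype(np.int8)
    m = np.vstack([base, base])
    haps = make_haps(m)
    pm = PopMap({f"s{i}": ("A" if i < 3 else "B") for i in range(6)})
    res = fst_weir_cockerham_window(haps, pm, "A", "B", Window("chr1", 0, 100))
    assert res.fst_raw <= 0.0
    assert res.fst_clamped == 0.0


def test_fst_components_match_hand_oracle(rng):
    """3 vs 3 individuals, random sites: a, b, c match the independent
    first-principles evaluation exactly."""
    for _ in range(20):
        ga = [(int(rng.integers(2)), int(rng.integers(2))) for _ in range(3)]
        gb = [(int(rng.integers(2)), int(rng.integers(2))) for _ in range(3)]
        alleles = [a for g in ga + gb for a in g]
        if len(set(alleles)) < 2:
            continue
        n = np.array([3.0, 3.0])
        p = np.array(
            [sum(a + b for a, b in ga) / 6.0, sum(a + b for a, b in gb) / 6.0]
        )
        h = np.array(
            [sum(a != b for a, b in ga) / 3.0, sum(a != b for a, b in gb) / 3.0]
        )
        comp = wc_site_components(n, p, h)
        ea, eb, ec = oracle_wc(ga, gb)
        assert comp.a == pytest.approx(ea, abs=1e-12)
        assert comp.b == pytest.approx(eb, abs=1e-12)
        assert comp.c == pytest.approx(ec, abs=1e-12)


def test_fst_window_ratio_of_sums(rng):
    """Window estimate equals sum(a)/sum(a+b+c) over informative sites."""
    haps = random_haps(rng, 6, 10, length=200)
    pm = PopMap({f"s{i}": ("A" if i < 3 else "B") for i in range(6)})
    res = fst_weir_cockerham_window(haps, pm, "A", "B", Window("chr1", 0, 200))
    sum_a = sum_abc = 0.0
    for j in range(10):
        ga = [(int(haps.matrix[2 * i, j]), int(haps.matrix[2 * i + 1, j])) for i in range(3)]
        gb = [
            (int(haps.matrix[2 * i, j]), int(haps.matrix[2 * i + 1, j])) for i in range(3, 6)
        ]
        a, b, c = oracle_wc(ga, gb)
        if a + b + c != 0:
            sum_a += a
            sum_abc += a + b + c
    assert res.fst_raw == pytest.approx(sum_a / sum_abc, abs=1e-12)


def test_fst_no_informative_sites_flagged():
    m = np.zeros((8, 2), dtype=np.int8)
    haps = make_haps(m)
    pm = PopMap({f"s{i}": ("A" if i < 2 else "B") for i in range(4)})
    res = fst_weir_cockerham_window(haps, pm, "A", "B", Window("chr1", 0, 100))
    assert not res.defined


# --- PBS --------------------------------------------------------------------


def test_pbs_closed_forms():
    assert pbs_from_fst(0.0, 0.0, 0.0) == (0.0, 0.0, 0.0)
    pbs_a, pbs_b, pbs_c = pbs_from_fst(0.5, 0.5, 0.0)
    assert pbs_a == pytest.approx(math.log(2), abs=1e-12)
    assert pbs_b == pytest.approx(0.0, abs=1e-12)
    assert pbs_c == pytest.approx(0.0, abs=1e-12)


def test_pbs_symmetry_under_bc_permutation():
    a1, _, _ = pbs_from_fst(0.3, 0.6, 0.2)
    a2, _, _ = pbs_from_fst(0.6, 0.3, 0.2)
    assert a1 == pytest.approx(a2, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.floats(0, 0.99),
    st.floats(0, 0.99),
    st.floats(0, 0.99),
)
def test_pbs_branch_sum_conservation(fab, fac, fbc):
    """pbs_a + pbs_b + pbs_c = (T_ab + T_ac + T_bc) / 2 exactly."""
    pa, pb, pc = pbs_from_fst(fab, fac, fbc)
    t = [-math.log(1 - min(f, 0.995)) for f in (fab, fac, fbc)]
    assert pa + pb + pc == pytest.approx(sum(t) / 2, abs=1e-12)


def test_pbs_cap_keeps_values_finite():
    pa, pb, pc = pbs_from_fst(1.0, 1.0, 1.0)
    assert all(map(math.isfinite, (pa, pb, pc)))


# --- quantiles --------------------------------------------------------------


def test_nearest_rank_quantiles():
    values = np.arange(1, 101)
    assert empirical_quantile_threshold(values, "upper", 0.01) == 100
    assert empirical_quantile_threshold(values, "lower", 0.01) == 1
    with pytest.raises(ValueError):
        empirical_quantile_threshold([], "upper")
    with pytest.raises(ValueError):
        empirical_quantile_threshold([1.0], "middle")


def test_upper_quantile_exceedance_count(rng):
    draws = rng.random(1000)
    thr = empirical_quantile_threshold(draws, "upper", 0.01)
    assert (draws >= thr).sum() == 10


def test_quantiles_ignore_nan():
    vals = [math.nan, 1.0, 2.0, 3.0]
    assert empirical_quantile_threshold(vals, "upper", 0.5) == 2.0


def test_island_model_fst_matches_coalescent_expectation():
    """Two-deme symmetric island model: mean window Fst approaches the
    coalescent closed form 1/(1 + 8*N*m) (two demes: between-deme
    coalescence waits 1/(2m) to migrate on top of the 4N background)."""
    import msprime

    n_deme, mig = 5000, 5e-5  # 8Nm = 2 -> expected Fst = 1/3
    dem = msprime.Demography()
    dem.add_population(name="d1", initial_size=n_deme)
    dem.add_population(name="d2", initial_size=n_deme)
    dem.set_symmetric_migration_rate(["d1", "d2"], mig)
    vals = []
    pm = PopMap({f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)})
    for seed in range(1, 61):
        ts = msprime.sim_ancestry(
            samples=[msprime.SampleSet(5, population="d1", ploidy=2),
                     msprime.SampleSet(5, population="d2", ploidy=2)],
            demography=dem, sequence_length=20_000,
            recombination_rate=1e-8, random_seed=seed,
        )
        ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=seed + 1000)
        g = ts.genotype_matrix().T.astype(np.int8)
        keep = [j for j, v in enumerate(ts.variants()) if len(v.alleles) == 2]
        pos = np.array([int(ts.site(j).position) + 1 for j in keep])
        uniq = np.concatenate([[True], np.diff(pos) > 0])
        from conftest import make_haps
        haps = make_haps(
            g[:, keep][:, uniq], positions=pos[uniq],
            samples=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)],
        )
        res = fst_weir_cockerham_window(haps, pm, "A", "B", Window("chr1", 0, 20_000))
        if res.defined:
            vals.append(res.fst_raw)
    expected = 1.0 / (1.0 + 8 * n_deme * mig)
    se = float(np.std(vals, ddof=1)) / math.sqrt(len(vals))
    assert abs(float(np.mean(vals)) - expected) <= max(3 * se, 0.03)
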