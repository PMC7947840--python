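import numpy as np
import pytest

from guenonscan.variant_io import HaplotypeSet, PopMap


def make_haps(matrix, positions=None, chrom="chr1", samples=None):
    """Build a HaplotypeSet from a (haplotypes x sites) 0/1/-1 array."""
    matrix = np.asarray(matrix, dtype=np.int8)
    n_samples = matrix.shape[0] // 2
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if positions is None:
        positions = np.arange(1, matrix.shape[1] + 1)
    return HaplotypeSet(
        samples=samples,
        chroms=np.array([chrom] * matrix.shape[1], dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        matrix=matrix,
    )


def random_haps(rng, n_samples, n_sites, missing_frac=0.0, length=None):
    """Random phased cohort on one chromosome for property tests."""
    m = rng.integers(0, 2, size=(2 * n_samples, n_sites)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random(m.shape) < missing_frac
        m[mask] = -1
    length = length or (n_sites * 10)
    positions = np.sort(rng.choice(np.arange(1, length + 1), size=n_sites, replace=False))
    return make_haps(m, positions=positions)


@pytest.fixture(scope="session")
def neutral_cohort():
    """Small neutral cohort (no ghost pulse), shared across tests."""
    from dataclasses import replace

    from guenonscan.synthetic_data import DemographyConfig, simulate_cohort

    cfg = replace(DemographyConfig(), ghost_fraction=0.0)
    return simulate_cohort(cfg, n_windows=12, window_bp=20_000, seed=101)


@pytest.fixture(scope="session")
def admixed_cohort():
    """Cohort with the default 10% ghost pulse into East."""
    from guenonscan.synthetic_data import DemographyConfig, simulate_cohort

    return simulate_cohort(DemographyConfig(), n_windows=60, window_bp=50_000, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def popmap_two():
    return PopMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
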