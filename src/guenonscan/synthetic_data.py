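"""Coalescent synthetic cohorts with the statistical structure the scan
assumes: three ingroup populations (East, WCa, WCb) plus an outgroup,
with an optional deep "ghost" donor lineage contributing an admixture
pulse into East, optional hard-sweep injection, and truth tracks.

The demography mirrors the inferred history of the mona monkey cohort:
the East and West-Central (WC) lineages split ~84.4 ka, WCa and WCb
split ~6.7 ka with ongoing symmetric migration, generation time 8.5 yr,
per-generation mutation rate 8.415e-9/bp and recombination 1 cM/Mb.
Windows are simulated independently (free recombination between windows,
1 cM/Mb within), so haplotype structure exists only within windows.
Ghost ancestry is tracked through a census event just above the pulse
time and emitted per haplotype as truth tracts.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import msprime
import numpy as np

from .variant_io import (
    GenomeMask,
    HaplotypeSet,
    PopMap,
    VariantSite,
    write_vcf,
)

_DEFAULT_NE = {
    "East": 20_000,
    "WCa": 20_000,
    "WCb": 20_000,
    "WC": 30_000,  # WC ancestor
    "MONA": 40_000,  # East/WC ancestor
    "Ghost": 30_000,
    "Outgroup": 30_000,
    "ANC_GHOST": 40_000,
    "ROOT": 40_000,
}

_DEFAULT_SAMPLES = {"East": 5, "WCa": 4, "WCb": 4, "Outgroup": 1}


@dataclass
class DemographyConfig:
    """Generative model for synthetic cohorts (times in years)."""

    ne: dict = field(default_factory=lambda: dict(_DEFAULT_NE))
    t_east_wc_years: float = 84_400.0
    t_wca_wcb_years: float = 6_700.0
    t_ghost_years: float = 3.0e6
    t_outgroup_years: float = 3.5e6
    t_pulse_years: float = 40_000.0
    ghost_fraction: float = 0.10
    wc_migration: float = 1e-4  # symmetric WCa<->WCb, per generation
    ancestral_migration: float = 0.0  # optional East<->WC-ancestor band
    mutation_rate_per_gen: float = 8.415e-9
    generation_time_years: float = 8.5
    recomb_per_bp_per_gen: float = 1e-8  # 1 cM/Mb
    samples: dict = field(default_factory=lambda: dict(_DEFAULT_SAMPLES))

    def validate(self) -> None:
        if not (0.0 <= self.ghost_fraction < 1.0):
            raise ValueError("ghost_fraction must be in [0, 1)")
        if self.ghost_fraction > 0 and not (
            self.t_pulse_years < self.t_east_wc_years < self.t_ghost_years
        ):
            raise ValueError("need t_pulse < t_east_wc < t_ghost")
        if not self.t_wca_wcb_years < self.t_east_wc_years:
            raise ValueError("WCa/WCb split must predate the East/WC split (backwards)")
        if not self.t_ghost_years < self.t_outgroup_years:
            raise ValueError("ghost split must be younger than the outgroup split")
        for k, v in (("mutation", self.mutation_rate_per_gen), ("recomb", self.recomb_per_bp_per_gen)):
            if v < 0:
                raise ValueError(f"{k} rate must be >= 0")

    def generations(self, years: float) -> float:
        return years / self.generation_time_years

    @property
    def census_time_gen(self) -> float:
        return self.generations(self.t_pulse_years) + 1.0

    def to_msprime(self) -> msprime.Demography:
        self.validate()
        dem = msprime.Demography()
        for name in ("East", "WCa", "WCb", "Outgroup", "Ghost", "WC", "MONA", "ANC_GHOST", "ROOT"):
            dem.add_population(name=name, initial_size=self.ne[name])
        if self.wc_migration > 0:
            dem.set_symmetric_migration_rate(["WCa", "WCb"], self.wc_migration)
        if self.ancestral_migration > 0:
            dem.set_symmetric_migration_rate(["East", "WC"], self.ancestral_migration)
        if self.ghost_fraction > 0:
            dem.add_mass_migration(
                time=self.generations(self.t_pulse_years),
                source="East",
                dest="Ghost",
                proportion=self.ghost_fraction,
            )
        dem.add_census(time=self.census_time_gen)
        dem.add_population_split(
            time=self.generations(self.t_wca_wcb_years), derived=["WCa", "WCb"], ancestral="WC"
        )
        dem.add_population_split(
            time=self.generations(self.t_east_wc_years), derived=["East", "WC"], ancestral="MONA"
        )
        dem.add_population_split(
            time=self.generations(self.t_ghost_years),
            derived=["MONA", "Ghost"],
            ancestral="ANC_GHOST",
        )
        dem.add_population_split(
            time=self.generations(self.t_outgroup_years),
            derived=["ANC_GHOST", "Outgroup"],
            ancestral="ROOT",
        )
        dem.sort_events()
        return dem


@dataclass
class TruthTracks:
    """Simulator-emitted ground truth used as the acceptance oracle."""

    # (sample, haplotype 0/1) -> list of (chrom, start, end) ghost tracts
    ghost_tracts: dict = field(default_factory=dict)
    sweep_sites: list = field(default_factory=list)  # (chrom, pos, carrier_frac)
    window_labels: list = field(default_factory=list)  # "neutral" | "sweep" per window

    def tract_bp(self, sample: str) -> int:
        total = 0
        for h in (0, 1):
            total += sum(e - s for _, s, e in self.ghost_tracts.get((sample, h), []))
        return total

    def ghost_fraction_of(self, sample: str, genome_bp: int) -> float:
        return self.tract_bp(sample) / (2 * genome_bp)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for (sample, h), tracts in sorted(self.ghost_tracts.items()):
                for chrom, s, e in tracts:
                    fh.write(f"{chrom}\t{s}\t{e}\t{sample}|{h}\n")


@dataclass
class Cohort:
    """A simulated phased cohort plus everything needed to analyse it."""

    haps: HaplotypeSet
    sites: list
    popmap: PopMap
    truth: TruthTracks
    contig_lengths: dict
    config: DemographyConfig
    window_bp: int

    @property
    def windows(self):
        from .variant_io import make_windows

        return make_windows(self.contig_lengths, self.window_bp)

    @property
    def callable_mask(self) -> GenomeMask:
        return GenomeMask.full(self.contig_lengths)


def _ghost_tracts_for_tree_sequence(ts, config, east_nodes) -> dict:
    """Per-haplotype genomic segments whose census-time ancestor sits in
    the Ghost population."""
    t_census = config.census_time_gen
    nodes_time = ts.tables.nodes.time
    nodes_pop = ts.tables.nodes.population
    ghost_pop = [p.id for p in ts.populations() if p.metadata.get("name") == "Ghost"][0]
    raw: dict = {u: [] for u in east_nodes}
    for tree in ts.trees():
        left, right = tree.interval
        for u in east_nodes:
            v = u
            while v != -1 and nodes_time[v] < t_census:
                v = tree.parent(v)
            if v != -1 and nodes_time[v] == t_census and nodes_pop[v] == ghost_pop:
                raw[u].append((left, right))
    merged: dict = {}
    for u, ivs in raw.items():
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[u] = out
    return merged


def simulate_cohort(
    config: DemographyConfig | None = None,
    n_windows: int = 50,
    window_bp: int = 50_000,
    seed: int = 1,
    chrom: str = "chr1",
) -> Cohort:
    """Simulate independent coalescent windows under the configured
    demography and concatenate them on one synthetic contig.

    Returns an in-memory :class:`Cohort`; ``write_fixture_bundle`` writes
    the same content as VCF/TSV/BED files. Fully reproducible per seed.
    """
    config = config or DemographyConfig()
    config.validate()
    dem = config.to_msprime()
    sample_sets = [
        msprime.SampleSet(n, population=pop, ploidy=2)
        for pop, n in config.samples.items()
        if n > 0
    ]
    sample_ids = []
    popmap = PopMap()
    for pop, n in config.samples.items():
        for i in range(n):
            name = f"{pop}_{i + 1}"
            sample_ids.append(name)
            popmap[name] = pop

    rng = np.random.default_rng(seed)
    anc_seeds = rng.integers(1, 2**31 - 1, size=n_windows)
    mut_seeds = rng.integers(1, 2**31 - 1, size=n_windows)

    chroms_all, pos_all, cols_all = [], [], []
    sites: list = []
    truth = TruthTracks()
    n_hap = 2 * len(sample_ids)
    track_ghost = config.ghost_fraction > 0
    east_hap_rows = None

    for w in range(n_windows):
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=dem,
            sequence_length=window_bp,
            recombination_rate=config.recomb_per_bp_per_gen,
            random_seed=int(anc_seeds[w]),
        )
        ts = msprime.sim_mutations(
            ts, rate=config.mutation_rate_per_gen, random_seed=int(mut_seeds[w])
        )
        offset = w * window_bp
        # sample node u corresponds to haplotype row u (msprime orders
        # sample nodes by sample set, two per diploid individual)
        if track_ghost:
            if east_hap_rows is None:
                east_hap_rows = [
                    r
                    for i, s in enumerate(sample_ids)
                    if popmap[s] == "East"
                    for r in (2 * i, 2 * i + 1)
                ]
            tracts = _ghost_tracts_for_tree_sequence(ts, config, east_hap_rows)
            for u, ivs in tracts.items():
                sample = sample_ids[u // 2]
                key = (sample, u % 2)
                lst = truth.ghost_tracts.setdefault(key, [])
                for s, e in ivs:
                    gs, ge = offset + int(s), offset + int(math.ceil(e))
                    if lst and lst[-1][2] >= gs and lst[-1][0] == chrom:
                        lst[-1] = (chrom, lst[-1][1], max(lst[-1][2], ge))
                    else:
                        lst.append((chrom, gs, ge))
        last_pos = -1
        for var in ts.variants():
            if len(var.alleles) != 2:
                continue  # multiallelic under finite sites: drop
            pos = int(var.site.position)
            if pos == last_pos:
                continue
            last_pos = pos
            gpos = offset + pos + 1  # 1-based
            chroms_all.append(chrom)
            pos_all.append(gpos)
            cols_all.append(var.genotypes.astype(np.int8))
            sites.append(
                VariantSite(
                    chrom=chrom,
                    pos=gpos,
                    ref_allele=var.alleles[0],
                    alt_allele=var.alleles[1],
                    qual=100.0,
                    n_called=len(sample_ids),
                )
            )
        truth.window_labels.append("neutral")

    matrix = (
        np.stack(cols_all, axis=1) if cols_all else np.zeros((n_hap, 0), dtype=np.int8)
    )
    haps = HaplotypeSet(
        samples=sample_ids,
        chroms=np.array(chroms_all, dtype=object),
        positions=np.array(pos_all, dtype=np.int64),
        matrix=matrix,
    )
    contig_lengths = {chrom: n_windows * window_bp}
    return Cohort(haps, sites, popmap, truth, contig_lengths, config, window_bp)


def inject_sweep(
    cohort: Cohort,
    target_pop: str = "East",
    site_index: int | None = None,
    window_index: int | None = None,
    carrier_frac: float = 0.95,
    tract_mean_bp: float = 200_000.0,
    theta_sweep: float = 1e-5,
    seed: int = 1,
) -> Cohort:
    """Inject a hard selective sweep by haplotype copying.

    One donor haplotype carrying the selected allele is copied onto
    ceil(carrier_frac * n) target-population haplotypes over an interval
    around the site (exponential endpoints, mean ``tract_mean_bp``/2 per
    side), then new private mutations are sprinkled on copied tracts at
    rate ``theta_sweep`` per bp to model post-sweep mutation (the default
    1e-5/bp is the mutation input mu*t of a sweep ~10 ka old). A star-like
    approximation to a completed sweep, adequate to create the low-pi /
    high-PBS / high-XP-EHH signal class a scan must detect.
    """
    rng = np.random.default_rng(seed)
    haps = cohort.haps
    if site_index is None:
        windows = cohort.windows
        w = windows[window_index if window_index is not None else len(windows) // 2]
        idx = haps.window_site_indices(w)
        rows = haps.population_rows(cohort.popmap, target_pop)
        # pick a mid-frequency segregating site near the window centre
        best, best_score = None, -1.0
        centre = (w.start + w.end) / 2
        for j in idx:
            p = haps.allele_frequency(rows, int(j))
            if not (0.0 < p < 1.0):
                continue
            score = min(p, 1 - p) - abs(haps.positions[j] - 1 - centre) / (10 * w.length)
            if score > best_score:
                best, best_score = int(j), score
        if best is None:
            raise ValueError("no segregating site available in target window")
        site_index = best
    rows = haps.population_rows(cohort.popmap, target_pop)
    col = haps.matrix[rows, site_index]
    carriers_of_allele = rows[col == 1]
    if len(carriers_of_allele) == 0 or (col == 1).all():
        raise ValueError("selected site must be segregating in the target population")
    donor = int(carriers_of_allele[rng.integers(len(carriers_of_allele))])
    n_copy = math.ceil(carrier_frac * len(rows))
    chosen = rng.choice(rows, size=n_copy, replace=False)

    chrom = str(haps.chroms[site_index])
    site_pos0 = int(haps.positions[site_index]) - 1
    pos0 = haps.positions - 1
    new_cols = []  # (pos0, row) singleton mutations added post-copy
    matrix = haps.matrix.copy()
    for r in chosen:
        left = site_pos0 - rng.exponential(tract_mean_bp / 2.0)
        right = site_pos0 + rng.exponential(tract_mean_bp / 2.0)
        in_tract = (haps.chroms == chrom) & (pos0 >= left) & (pos0 <= right)
        matrix[r, in_tract] = matrix[donor, in_tract]
        if theta_sweep > 0:
            tract_len = max(right - left, 0.0)
            n_new = rng.poisson(theta_sweep * tract_len)
            for _ in range(n_new):
                p = int(rng.uniform(max(left, 0), right))
                new_cols.append((p, int(r)))

    chroms = haps.chroms
    positions = haps.positions
    if new_cols:
        add_pos = sorted({p for p, _ in new_cols if p + 1 not in set(haps.positions.tolist())})
        rows_at = {p: [r for q, r in new_cols if q == p] for p in add_pos}
        extra = np.zeros((matrix.shape[0], len(add_pos)), dtype=np.int8)
        for k, p in enumerate(add_pos):
            extra[rows_at[p], k] = 1
        positions = np.concatenate([positions, np.array(add_pos, dtype=np.int64) + 1])
        chroms = np.concatenate([chroms, np.array([chrom] * len(add_pos), dtype=object)])
        matrix = np.concatenate([matrix, extra], axis=1)
        order = np.argsort(positions, kind="stable")
        positions, chroms, matrix = positions[order], chroms[order], matrix[:, order]

    new_haps = HaplotypeSet(
        samples=list(haps.samples), chroms=chroms, positions=positions, matrix=matrix
    )
    truth = cohort.truth
    truth.sweep_sites.append((chrom, site_pos0 + 1, carrier_frac))
    w_idx = site_pos0 // cohort.window_bp
    if w_idx < len(truth.window_labels):
        truth.window_labels[w_idx] = "sweep"
    sites = [
        VariantSite(chrom=str(c), pos=int(p), ref_allele="A", alt_allele="T", qual=100.0,
                    n_called=new_haps.n_samples)
        for c, p in zip(new_haps.chroms, new_haps.positions)
    ]
    return Cohort(
        new_haps, sites, cohort.popmap, truth, cohort.contig_lengths, cohort.config,
        cohort.window_bp,
    )


SCENARIOS = ("neutral", "admixed", "swept", "full")


def write_fixture_bundle(out_dir, scenario: str = "neutral", seed: int = 1,
                         n_windows: int = 30, window_bp: int = 50_000,
                         force: bool = False) -> dict:
    """Write a small reproducible fixture bundle (VCF, popmap, masks,
    toy gene BED, truth tracks, checksums)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (pass force=True to overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    config = DemographyConfig()
    if scenario in ("neutral", "swept"):
        config = replace(config, ghost_fraction=0.0)
    cohort = simulate_cohort(config, n_windows=n_windows, window_bp=window_bp, seed=seed)
    if scenario in ("swept", "full"):
        cohort = inject_sweep(cohort, seed=seed)

    paths = {
        "vcf": out / "cohort.vcf",
        "popmap": out / "popmap.tsv",
        "callable": out / "callable.bed",
        "repeats": out / "repeats.bed",
        "genes": out / "genes.bed",
        "truth_ghost": out / "truth_ghost.bed",
        "truth_sweep": out / "truth_sweep.tsv",
        "checksums": out / "checksums.json",
    }
    write_vcf(cohort.haps, cohort.sites, paths["vcf"], cohort.contig_lengths)
    cohort.popmap.to_tsv(paths["popmap"])
    cohort.callable_mask.to_bed(paths["callable"])
    # toy repeat mask: one 2-kb repeat per fifth window
    chrom = next(iter(cohort.contig_lengths))
    with open(paths["repeats"], "w") as fh:
        for w in range(0, n_windows, 5):
            s = w * window_bp + window_bp // 4
            fh.write(f"{chrom}\t{s}\t{s + 2000}\n")
    # toy genes: one 10-kb gene per third window
    with open(paths["genes"], "w") as fh:
        for k, w in enumerate(range(0, n_windows, 3)):
            s = w * window_bp + window_bp // 3
            fh.write(f"{chrom}\t{s}\t{s + 10_000}\tgene{k + 1}\n")
    cohort.truth.to_bed(paths["truth_ghost"])
    with open(paths["truth_sweep"], "w") as fh:
        fh.write("chrom\tpos\tcarrier_frac\n")
        for c, p, f in cohort.truth.sweep_sites:
            fh.write(f"{c}\t{p}\t{f}\n")
    checksums = {
        name: hashlib.sha256(p.read_bytes()).hexdigest()
        for name, p in paths.items()
        if name != "checksums"
    }
    paths["checksums"].write_text(json.dumps(checksums, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
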