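"""Read, filter and window phased variant data and genomic masks.

All coordinate conventions live here: internal coordinates are 0-based
half-open; VCF positions (1-based) and BED intervals (0-based half-open)
are converted at the I/O boundary only.

The central container is :class:`HaplotypeSet`, a phased 0/1 allele matrix
(haplotypes x sites) that every downstream statistic consumes.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

MISSING = -1  # missing-allele code in the haplotype matrix

VALID_ALLELES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantSite:
    """A biallelic SNP record (VCF convention: ``pos`` is 1-based)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float = math.inf
    near_indel_bp: float = math.inf  # distance to the nearest indel call
    n_called: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")


@dataclass
class FilterConfig:
    """Site-level filter thresholds.

    Defaults mirror a conservative resequencing pipeline: drop SNPs within
    6 bp of a predicted indel, QUAL < 40, non-biallelic records, and sites
    genotyped in fewer than 95% of samples.
    """

    indel_radius_bp: int = 6
    min_qual: float = 40.0
    max_missing_frac: float = 0.05
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if self.indel_radius_bp < 0:
            raise ValueError("indel_radius_bp must be >= 0")
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")


@dataclass
class Window:
    """Genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int
    n_snps: int = 0
    is_partial: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end must exceed start: [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class PopMap(dict):
    """sample id -> population label mapping.

    A thin ``dict`` subclass; labels are free-form (the cohort convention
    is East / WCa / WCb / Outgroup).
    """

    @classmethod
    def from_tsv(cls, path) -> "PopMap":
        pm = cls()
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>population'")
                pm[parts[0]] = parts[1]
        return pm

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sample, pop in self.items():
                fh.write(f"{sample}\t{pop}\n")

    def samples_in(self, *populations: str) -> list:
        wanted = set(populations)
        return [s for s, p in self.items() if p in wanted]

    @property
    def populations(self) -> list:
        seen = []
        for p in self.values():
            if p not in seen:
                seen.append(p)
        return seen


@dataclass
class HaplotypeSet:
    """Phased 0/1 allele matrix: 2*n_samples rows x n_sites columns.

    ``matrix`` codes 0 = reference allele, 1 = alternate, -1 = missing.
    Rows 2i and 2i+1 are the two haplotypes of ``samples[i]``.
    Columns are sorted by (chrom, pos); ``positions`` are 1-based.
    """

    samples: list
    chroms: np.ndarray  # per-site contig id (object dtype)
    positions: np.ndarray  # per-site 1-based position (int64)
    matrix: np.ndarray  # int8, shape (2*n_samples, n_sites)

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 2 * len(self.samples):
            raise ValueError("matrix must have 2 rows per sample")
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("matrix column count must match positions")
        for chrom in dict.fromkeys(self.chroms):
            pos = self.positions[self.chroms == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sample_rows(self, sample: str) -> tuple:
        i = self.samples.index(sample)
        return 2 * i, 2 * i + 1

    def population_rows(self, popmap: PopMap, *populations: str) -> np.ndarray:
        rows = []
        for s in popmap.samples_in(*populations):
            if s in self.samples:
                rows.extend(self.sample_rows(s))
        return np.asarray(sorted(rows), dtype=np.intp)

    def site_mask_subset(self, keep: np.ndarray) -> "HaplotypeSet":
        return HaplotypeSet(
            samples=list(self.samples),
            chroms=self.chroms[keep],
            positions=self.positions[keep],
            matrix=self.matrix[:, keep],
        )

    def window_site_indices(self, window: Window) -> np.ndarray:
        """Indices of sites inside a 0-based half-open window."""
        on_chrom = self.chroms == window.chrom
        zero_based = self.positions - 1
        return np.flatnonzero(on_chrom & (zero_based >= window.start) & (zero_based < window.end))

    def allele_frequency(self, rows: np.ndarray, site: int) -> float:
        """Alt-allele frequency over called haplotypes; NaN if none called."""
        col = self.matrix[rows, site]
        called = col != MISSING
        n = int(called.sum())
        return float(col[called].sum()) / n if n else math.nan


@dataclass
class GenomeMask:
    """Per-chrom sets of 0-based half-open intervals with a role tag."""

    intervals: dict = field(default_factory=dict)  # chrom -> (k, 2) int array
    role: str = "callable"

    def __post_init__(self) -> None:
        self.intervals = {c: _normalize_intervals(iv) for c, iv in self.intervals.items()}

    @classmethod
    def from_bed(cls, path, role: str = "callable") -> "GenomeMask":
        per_chrom: dict = {}
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed BED line")
                per_chrom.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
        return cls({c: np.array(v, dtype=np.int64) for c, v in per_chrom.items()}, role=role)

    @classmethod
    def full(cls, contig_lengths: dict, role: str = "callable") -> "GenomeMask":
        return cls(
            {c: np.array([[0, length]], dtype=np.int64) for c, length in contig_lengths.items()},
            role=role,
        )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    def total_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return 0
        lo = np.minimum(iv[:, 1], end)
        hi = np.maximum(iv[:, 0], start)
        return int(np.clip(lo - hi, 0, None).sum())

    def intersects(self, chrom: str, start: int, end: int) -> bool:
        return self.overlap_bp(chrom, start, end) > 0

    def contains_point(self, chrom: str, pos0: int) -> bool:
        return self.intersects(chrom, pos0, pos0 + 1)

    def padded(self, flank_bp: int) -> "GenomeMask":
        return GenomeMask(
            {
                c: np.column_stack([np.maximum(iv[:, 0] - flank_bp, 0), iv[:, 1] + flank_bp])
                for c, iv in self.intervals.items()
            },
            role=self.role,
        )


@dataclass
class FilterReport:
    """Per-rule removal accounting; counts partition the input sites."""

    n_input: int
    removed_near_indel: int = 0
    removed_low_qual: int = 0
    removed_not_biallelic: int = 0
    removed_missingness: int = 0
    n_retained: int = 0

    def check_partition(self) -> bool:
        removed = (
            self.removed_near_indel
            + self.removed_low_qual
            + self.removed_not_biallelic
            + self.removed_missingness
        )
        return removed + self.n_retained == self.n_input


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_vcf_with_popmap(vcf_path, popmap_path):
    """Read a phased multi-sample VCF and its sample->population map.

    Returns ``(sites, haps, popmap)``. Only biallelic SNP records become
    columns of the HaplotypeSet; indel records are consumed to populate
    per-site ``near_indel_bp`` distances. Heterozygous genotypes must be
    phased ("0|1"); an unphased het raises with the offending sample/site.
    """
    from cyvcf2 import VCF

    popmap = PopMap.from_tsv(popmap_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in popmap:
            raise ValueError(f"sample {s!r} missing from popmap {popmap_path}")

    sites: list = []
    columns: list = []
    indel_pos: dict = {}
    for rec in vcf:
        alts = rec.ALT or []
        is_snp_biallelic = (
            len(alts) == 1
            and len(rec.REF) == 1
            and len(alts[0]) == 1
            and rec.REF in VALID_ALLELES
            and alts[0] in VALID_ALLELES
        )
        if not is_snp_biallelic:
            # indels feed the proximity filter; multiallelic SNPs are dropped
            if len(rec.REF) != 1 or any(len(a) != 1 for a in alts):
                indel_pos.setdefault(rec.CHROM, []).append(rec.POS)
            continue
        col = np.full(2 * len(samples), MISSING, dtype=np.int8)
        n_called = 0
        for i, gt in enumerate(rec.genotypes):
            a0, a1, phased = gt[0], gt[1], bool(gt[2])
            if a0 >= 0 and a1 >= 0:
                if a0 != a1 and not phased:
                    raise ValueError(
                        f"unphased heterozygote for sample {samples[i]!r} "
                        f"at {rec.CHROM}:{rec.POS}"
                    )
                col[2 * i], col[2 * i + 1] = a0, a1
                n_called += 1
        sites.append(
            VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=alts[0],
                qual=rec.QUAL if rec.QUAL is not None else math.inf,
                n_called=n_called,
            )
        )
        columns.append(col)

    # distance to nearest indel, per chromosome
    for chrom, ipos in indel_pos.items():
        arr = np.sort(np.asarray(ipos, dtype=np.int64))
        for site in sites:
            if site.chrom != chrom:
                continue
            j = np.searchsorted(arr, site.pos)
            d = math.inf
            if j < len(arr):
                d = min(d, abs(int(arr[j]) - site.pos))
            if j > 0:
                d = min(d, abs(int(arr[j - 1]) - site.pos))
            site.near_indel_bp = min(site.near_indel_bp, d)

    if columns:
        matrix = np.stack(columns, axis=1)
        chroms = np.array([s.chrom for s in sites], dtype=object)
        positions = np.array([s.pos for s in sites], dtype=np.int64)
    else:
        matrix = np.zeros((2 * len(samples), 0), dtype=np.int8)
        chroms = np.array([], dtype=object)
        positions = np.array([], dtype=np.int64)
    haps = HaplotypeSet(samples=samples, chroms=chroms, positions=positions, matrix=matrix)
    return sites, haps, popmap


def apply_site_filters(sites, haps: HaplotypeSet, config: FilterConfig | None = None):
    """Apply the four site filters; returns ``(sites, haps, FilterReport)``.

    A removed site is charged to the FIRST rule it fails, in the order
    indel-proximity, quality, biallelic, missingness, so the per-rule
    counts plus retained sites partition the input.
    """
    config = config or FilterConfig()
    report = FilterReport(n_input=len(sites))
    n_samples = haps.n_samples
    keep = np.ones(len(sites), dtype=bool)
    for i, site in enumerate(sites):
        if site.near_indel_bp <= config.indel_radius_bp:
            report.removed_near_indel += 1
            keep[i] = False
        elif site.qual < config.min_qual:
            report.removed_low_qual += 1
            keep[i] = False
        elif config.biallelic_only and (
            site.ref_allele not in VALID_ALLELES or site.alt_allele not in VALID_ALLELES
        ):
            report.removed_not_biallelic += 1
            keep[i] = False
        elif n_samples and site.n_called < (1.0 - config.max_missing_frac) * n_samples:
            report.removed_missingness += 1
            keep[i] = False
    report.n_retained = int(keep.sum())
    kept_sites = [s for s, k in zip(sites, keep) if k]
    return kept_sites, haps.site_mask_subset(keep), report


def make_windows(contig_lengths: dict, size_bp: int) -> list:
    """Tile each contig with non-overlapping windows of ``size_bp``.

    A trailing partial window is kept and flagged ``is_partial``.
    """
    if size_bp <= 0:
        raise ValueError("size_bp must be positive")
    windows = []
    for chrom, length in contig_lengths.items():
        start = 0
        while start < length:
            end = min(start + size_bp, length)
            windows.append(
                Window(chrom=chrom, start=start, end=end, is_partial=(end - start) < size_bp)
            )
            start = end
    return windows


def assign_window_snp_counts(windows: list, haps: HaplotypeSet) -> list:
    for w in windows:
        w.n_snps = int(len(haps.window_site_indices(w)))
    return windows


def select_neutral_windows(
    contig_lengths: dict,
    repeat_mask: GenomeMask,
    exon_mask: GenomeMask,
    window_bp: int = 50_000,
    flank_bp: int = 10_000,
    min_spacing_bp: int = 100_000,
    n: int = 10_000,
    seed: int = 0,
) -> list:
    """Randomly select putatively neutral windows.

    Windows must not intersect repeats, nor exons padded by ``flank_bp``,
    and accepted windows must be at least ``min_spacing_bp`` apart
    (gap between interval ends). Selection is reproducible per seed.
    """
    padded_exons = exon_mask.padded(flank_bp)
    candidates = [
        w
        for w in make_windows(contig_lengths, window_bp)
        if not w.is_partial
        and not repeat_mask.intersects(w.chrom, w.start, w.end)
        and not padded_exons.intersects(w.chrom, w.start, w.end)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    accepted: list = []
    per_chrom: dict = {}
    for idx in order:
        w = candidates[idx]
        ok = all(
            min(abs(w.start - o.end), abs(o.start - w.end)) >= min_spacing_bp
            for o in per_chrom.get(w.chrom, [])
        )
        if ok:
            accepted.append(w)
            per_chrom.setdefault(w.chrom, []).append(w)
            if len(accepted) >= n:
                break
    if len(accepted) < n:
        warnings.warn(
            f"only {len(accepted)} of {n} requested neutral windows qualify", stacklevel=2
        )
    accepted.sort(key=lambda w: (w.chrom, w.start))
    return accepted


def thin_snps(sites: list, interval_bp: int = 50_000) -> list:
    """Keep the first SNP of each ``interval_bp`` interval per chromosome."""
    kept = []
    seen: set = set()
    for site in sites:
        key = (site.chrom, (site.pos - 1) // interval_bp)
        if key not in seen:
            seen.add(key)
            kept.append(site)
    return kept


def pairwise_ibs(haps: HaplotypeSet, sample_a: str, sample_b: str) -> float:
    """Mean identity-by-state between two diploid genotypes, in [0, 1].

    Per co-called site the shared-allele fraction is 0, 0.5 or 1
    (1 - |dosage difference| / 2). Symmetric in its arguments.
    """
    ra = haps.sample_rows(sample_a)
    rb = haps.sample_rows(sample_b)
    ga = haps.matrix[list(ra), :]
    gb = haps.matrix[list(rb), :]
    called = (ga != MISSING).all(axis=0) & (gb != MISSING).all(axis=0)
    if not called.any():
        raise ValueError(f"no co-called sites between {sample_a!r} and {sample_b!r}")
    dos_a = ga[:, called].sum(axis=0)
    dos_b = gb[:, called].sum(axis=0)
    return float(np.mean(1.0 - np.abs(dos_a - dos_b) / 2.0))


def sample_random_regions(
    callable_mask: GenomeMask, n: int, length_bp: int, seed: int = 0
) -> list:
    """Sample ``n`` fixed-length regions uniformly inside the callable mask.

    Returns (chrom, start, end) tuples; fewer than ``n`` (with a warning)
    when no callable interval can hold a region of the requested length.
    """
    slots = []
    weights = []
    for chrom, ivs in callable_mask.intervals.items():
        for s, e in ivs:
            if e - s >= length_bp:
                slots.append((chrom, int(s), int(e)))
                weights.append(e - s - length_bp + 1)
    if not slots:
        warnings.warn("callable mask has no interval long enough; returning none", stacklevel=2)
        return []
    rng = np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float)
    picks = rng.choice(len(slots), size=n, p=w / w.sum())
    regions = []
    for k in picks:
        chrom, s, e = slots[k]
        start = int(rng.integers(s, e - length_bp + 1))
        regions.append((chrom, start, start + length_bp))
    return regions


def write_vcf(haps: HaplotypeSet, sites, path, contig_lengths: dict | None = None) -> None:
    """Write a minimal phased VCFv4.2 readable by standard parsers."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=guenonscan\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(haps.samples)
            + "\n"
        )
        for j, site in enumerate(sites):
            gts = []
            for i in range(haps.n_samples):
                a0, a1 = haps.matrix[2 * i, j], haps.matrix[2 * i + 1, j]
                f0 = "." if a0 == MISSING else str(int(a0))
                f1 = "." if a1 == MISSING else str(int(a1))
                gts.append(f"{f0}|{f1}")
            qual = "." if math.isinf(site.qual) else f"{site.qual:g}"
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t{site.alt_allele}"
                f"\t{qual}\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _normalize_intervals(iv) -> np.ndarray:
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)
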