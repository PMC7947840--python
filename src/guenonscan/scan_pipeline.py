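"""Selection-scan orchestration: quantile intersection of PBS, XP-EHH and
pi-ratio, region merging, gene annotation, the introgression dxy
contrast, and the end-to-end runner.

The candidate rule follows the scan convention: a window is a sweep
candidate when it is simultaneously in the upper q tail of PBS, the
upper q tail of mean normalized XP-EHH, and the lower q tail of the
focal/sister pi ratio (q = 0.01 by default); adjacent passing windows
are merged into regions.
"""

from __future__ import annotations

import math
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .popgen_stats import dxy, empirical_quantile_threshold
from .variant_io import GenomeMask, sample_random_regions


@dataclass
class ThresholdConfig:
    q_pbs: float = 0.01  # upper tail
    q_xpehh: float = 0.01  # upper tail
    q_pi: float = 0.01  # lower tail, on the focal/sister pi ratio
    merge_adjacent: bool = True

    def __post_init__(self) -> None:
        for q in (self.q_pbs, self.q_xpehh, self.q_pi):
            if not 0.0 < q < 1.0:
                raise ValueError("quantiles must be in (0, 1)")


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    max_pbs: float
    max_xpehh: float
    min_pi_ratio: float
    genes: list = field(default_factory=list)


def _merge_adjacent(rows: pd.DataFrame) -> list:
    """Merge directly adjacent windows (same chrom, start == previous end)."""
    regions = []
    for _, r in rows.sort_values(["chrom", "start"]).iterrows():
        if regions and regions[-1]["chrom"] == r["chrom"] and regions[-1]["end"] == r["start"]:
            regions[-1]["end"] = int(r["end"])
            regions[-1]["members"].append(r)
        else:
            regions.append(
                {"chrom": r["chrom"], "start": int(r["start"]), "end": int(r["end"]),
                 "members": [r]}
            )
    return regions


def call_high_divergence_regions(window_stats: pd.DataFrame, q: float = 0.01,
                                 stat: str = "pbs_focal") -> tuple:
    """Windows above the upper-q nearest-rank threshold of ``stat``,
    merged into regions.

    Returns (regions DataFrame, summary dict with the threshold, region
    count, total/min/max region length).
    """
    values = window_stats[stat]
    threshold = empirical_quantile_threshold(values, "upper", q)
    passing = window_stats[values >= threshold]
    regions = _merge_adjacent(passing)
    df = pd.DataFrame(
        [
            {"chrom": g["chrom"], "start": g["start"], "end": g["end"],
             "n_windows": len(g["members"]),
             "max_stat": max(m[stat] for m in g["members"])}
            for g in regions
        ]
    )
    lengths = (df["end"] - df["start"]).to_numpy() if len(df) else np.array([], dtype=int)
    summary = {
        "threshold": threshold,
        "n_regions": int(len(df)),
        "total_bp": int(lengths.sum()),
        "min_bp": int(lengths.min()) if len(lengths) else 0,
        "max_bp": int(lengths.max()) if len(lengths) else 0,
    }
    return df, summary


def call_sweep_candidates(window_stats: pd.DataFrame,
                          thresholds: ThresholdConfig | None = None) -> tuple:
    """Triple-intersection sweep candidates, merged and coordinate-sorted.

    ``window_stats`` must carry ``pbs_focal``, ``xpehh`` and ``pi_ratio``
    columns on a common window set; windows with an undefined statistic
    never pass. Returns (list of CandidateRegion, thresholds dict).
    """
    cfg = thresholds or ThresholdConfig()
    thr = {
        "pbs": empirical_quantile_threshold(window_stats["pbs_focal"], "upper", cfg.q_pbs),
        "xpehh": empirical_quantile_threshold(window_stats["xpehh"], "upper", cfg.q_xpehh),
        "pi_ratio": empirical_quantile_threshold(window_stats["pi_ratio"], "lower", cfg.q_pi),
    }
    passing = window_stats[
        (window_stats["pbs_focal"] >= thr["pbs"])
        & (window_stats["xpehh"] >= thr["xpehh"])
        & (window_stats["pi_ratio"] <= thr["pi_ratio"])
    ]
    if cfg.merge_adjacent:
        groups = _merge_adjacent(passing)
    else:
        groups = [
            {"chrom": r["chrom"], "start": int(r["start"]), "end": int(r["end"]), "members": [r]}
            for _, r in passing.iterrows()
        ]
    out = [
        CandidateRegion(
            chrom=str(g["chrom"]), start=g["start"], end=g["end"],
            n_windows=len(g["members"]),
            max_pbs=max(m["pbs_focal"] for m in g["members"]),
            max_xpehh=max(m["xpehh"] for m in g["members"]),
            min_pi_ratio=min(m["pi_ratio"] for m in g["members"]),
        )
        for g in groups
    ]
    out.sort(key=lambda r: (r.chrom, r.start))
    return out, thr


def read_gene_bed(path) -> pd.DataFrame:
    """Parse a 4+-column gene BED; malformed lines raise with the line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: gene BED needs chrom,start,end,name")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end must exceed start")
            rows.append({"chrom": parts[0], "start": start, "end": end, "gene": parts[3]})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def annotate_genes(regions, genes: pd.DataFrame) -> list:
    """Gene ids whose span intersects each region (half-open, strand-
    agnostic, de-duplicated). ``regions`` is an iterable of objects or
    mappings with chrom/start/end. Returns a list of gene-id lists and
    also fills ``genes`` on CandidateRegion inputs."""
    from intervaltree import IntervalTree

    trees: dict = {}
    for _, g in genes.iterrows():
        trees.setdefault(g["chrom"], IntervalTree()).addi(g["start"], g["end"], g["gene"])
    out = []
    for region in regions:
        chrom, start, end = _region_coords(region)
        tree = trees.get(chrom)
        hits = sorted({iv.data for iv in tree.overlap(start, end)}) if tree else []
        if isinstance(region, CandidateRegion):
            region.genes = hits
        out.append(hits)
    return out


def tile_region(chrom: str, start: int, end: int, tile_bp: int) -> list:
    """Full tiles of ``tile_bp`` within a region (remainder dropped)."""
    return [
        (chrom, s, s + tile_bp) for s in range(start, end - tile_bp + 1, tile_bp)
    ]


def dxy_introgression_contrast(
    haps, popmap, segments, callable_mask: GenomeMask,
    pop_a="East", pop_b=("WCa", "WCb"),
    region_len: int = 1000, seed: int = 0,
) -> dict:
    """Mean dxy over 1-kb tiles of introgressed segments vs matched
    random callable regions; fold = segments / random.

    ``segments`` is an iterable with chrom/start/end. The random set is
    matched in count and length and reproducible per seed.
    """
    tiles = []
    for seg in segments:
        chrom, start, end = _region_coords(seg)
        tiles.extend(tile_region(chrom, start, end, region_len))
    if not tiles:
        raise ValueError("no segment tiles of the requested length")
    random_regions = sample_random_regions(callable_mask, len(tiles), region_len, seed)
    mean_seg = float(np.mean([dxy(haps, popmap, pop_a, pop_b, t) for t in tiles]))
    mean_rand = (
        float(np.mean([dxy(haps, popmap, pop_a, pop_b, r) for r in random_regions]))
        if random_regions
        else math.nan
    )
    fold = mean_seg / mean_rand if mean_rand and mean_rand > 0 else math.nan
    return {
        "mean_dxy_segments": mean_seg,
        "mean_dxy_random": mean_rand,
        "fold": fold,
        "n_tiles": len(tiles),
    }


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_full_scan(config: dict, seed: int = 1, out_dir=None) -> dict:
    """Run filter -> windows -> stats -> xpehh -> candidates -> annotation
    -> hmm -> dxy contrast on a synthetic or file-based cohort.

    ``config`` keys (all optional, with defaults): ``scenario`` or
    ``vcf``/``popmap`` inputs, ``window_bp``, population labels
    ``focal``/``sister``/``outgroup``, ``thresholds`` (q values),
    ``hmm`` (cutoff, bin_bp), ``genes`` (BED path). Writes TSV/BED
    tables and a run log under ``out_dir`` when given. Any stage failure
    aborts with the stage name and cause.
    """
    from . import archaic_hmm, synthetic_data, variant_io
    from .haplotype_scan import normalize_and_window, xpehh_scan
    from .popgen_stats import three_population_window_table

    report: dict = {"seed": seed, "config": dict(config)}
    focal = config.get("focal", "East")
    sister = tuple(config.get("sister", ("WCa", "WCb")))
    outgroup = config.get("outgroup", "Outgroup")
    window_bp = int(config.get("window_bp", 50_000))

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    def load():
        if "vcf" in config:
            sites, haps, popmap = variant_io.read_vcf_with_popmap(
                config["vcf"], config["popmap"]
            )
            contig_lengths = config.get("contig_lengths") or {
                c: int(haps.positions[haps.chroms == c].max())
                for c in dict.fromkeys(haps.chroms)
            }
            mask = (
                GenomeMask.from_bed(config["callable_bed"])
                if "callable_bed" in config
                else GenomeMask.full(contig_lengths)
            )
            for label in (focal, *sister, outgroup):
                if label not in popmap.values():
                    raise ValueError(f"population {label!r} absent from popmap")
            return sites, haps, popmap, contig_lengths, mask, None
        cohort = synthetic_data.simulate_cohort(
            synthetic_data.DemographyConfig(),
            n_windows=int(config.get("n_windows", 40)),
            window_bp=window_bp,
            seed=seed,
        )
        if config.get("scenario", "full") in ("swept", "full"):
            cohort = synthetic_data.inject_sweep(cohort, seed=seed)
        return (cohort.sites, cohort.haps, cohort.popmap, cohort.contig_lengths,
                cohort.callable_mask, cohort)

    sites, haps, popmap, contig_lengths, mask, cohort = stage("load", load)
    sites, haps, filt = stage(
        "filter", lambda: variant_io.apply_site_filters(sites, haps, variant_io.FilterConfig())
    )
    report["filter"] = vars(filt)
    windows = stage("windows", lambda: variant_io.make_windows(contig_lengths, window_bp))
    stats = stage(
        "stats",
        lambda: three_population_window_table(haps, popmap, windows, focal, sister, outgroup),
    )
    raw = stage("xpehh", lambda: xpehh_scan(haps, popmap, focal, sister, windows=windows))
    xp = stage("xpehh", lambda: normalize_and_window(raw, windows))
    stats = stats.merge(xp[["chrom", "start", "end", "xpehh"]], on=["chrom", "start", "end"])
    candidates, thresholds = stage(
        "candidates", lambda: call_sweep_candidates(stats, ThresholdConfig())
    )
    report["thresholds"] = thresholds
    if "genes" in config:
        genes = stage("annotation", lambda: read_gene_bed(config["genes"]))
        stage("annotation", lambda: annotate_genes(candidates, genes))
    hmm_cfg = config.get("hmm", {})
    focal_sample = hmm_cfg.get("focal_sample") or popmap.samples_in(focal)[0]
    track = stage(
        "hmm",
        lambda: archaic_hmm.build_observations(
            haps, popmap, focal_sample, sister, mask, bin_bp=int(hmm_cfg.get("bin_bp", 1000))
        ),
    )
    params, loglik = stage(
        "hmm", lambda: archaic_hmm.train_hmm(track, seed=seed)
    )
    segments, _ = stage(
        "hmm",
        lambda: archaic_hmm.decode_segments(
            track, params, pp_cutoff=float(hmm_cfg.get("cutoff", 0.98))
        ),
    )
    report["hmm"] = {
        "focal_sample": focal_sample,
        "lambda_archaic": params.lam_archaic,
        "lambda_nonarchaic": params.lam_nonarchaic,
        "loglik": loglik,
        "n_segments": len(segments),
        "called_bp": int(sum(s.length_bp for s in segments)),
    }
    if segments:
        contrast = stage(
            "contrast",
            lambda: dxy_introgression_contrast(haps, popmap, segments, mask, focal, sister,
                                               seed=seed),
        )
        report["dxy_contrast"] = contrast
    report["candidates"] = [vars(c) for c in candidates]
    report["n_candidates"] = len(candidates)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stats.to_csv(out / "window_stats.tsv", sep="\t", index=False)
        raw.to_csv(out / "xpehh_sites.tsv", sep="\t", index=False)
        pd.DataFrame([vars(c) for c in candidates]).to_csv(
            out / "candidates.tsv", sep="\t", index=False
        )
        archaic_hmm.segments_to_bed(segments, out / "hmm_segments.bed")
        with open(out / "run_log.txt", "w") as fh:
            fh.write(f"guenonscan {__version__}\npython {platform.python_version()}\n")
            fh.write(f"seed {seed}\n")
            for k, v in sorted(config.items()):
                fh.write(f"config {k} = {v}\n")
    report["window_stats"] = stats
    return report


def plot_scan(window_stats: pd.DataFrame, path, stat: str = "pbs_focal") -> None:
    """Basic Manhattan-style export of one window statistic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 2.5))
    x = (window_stats["start"] + window_stats["end"]) / 2
    ax.scatter(x, window_stats[stat], s=6)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(stat)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _region_coords(region):
    if isinstance(region, (tuple, list)):
        return region[0], int(region[1]), int(region[2])
    if isinstance(region, dict):
        return region["chrom"], int(region["start"]), int(region["end"])
    return region.chrom, int(region.start), int(region.end)
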