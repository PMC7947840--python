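# guenonscan

Population-genomic selection and introgression scans for small phased
resequencing cohorts, built around the study design of the mona monkey
(*Cercopithecus mona*): three ingroup populations — East, WCa and WCb,
separated by a riverine barrier — plus one outgroup individual, with
evidence of an ancient admixture pulse into the East population from an
unsampled ("ghost") relative.

The package is for population geneticists who have a phased multi-sample
VCF, a sample-to-population map and optional genomic masks, and want the
standard small-cohort analysis stack in one tested library:

* **Windowed statistics** — nucleotide diversity π, between-population
  divergence d<sub>xy</sub>, Weir–Cockerham F<sub>ST</sub> (ratio of
  sums), and the population branch statistic
  PBS<sub>a</sub> = (T<sub>ab</sub> + T<sub>ac</sub> − T<sub>bc</sub>)/2
  with T = −ln(1 − F<sub>ST</sub>).
* **XP-EHH** — cross-population extended haplotype homozygosity,
  ln(iHH<sub>A</sub>/iHH<sub>B</sub>) per core SNP, z-normalized
  genome-wide and averaged per window.
* **Sweep candidates** — the intersection of top-1% PBS, top-1% XP-EHH
  and low-1% π-ratio windows, merged into regions and annotated with
  overlapping genes.
* **D-statistics** — frequency-based ABBA–BABA with weighted
  block-jackknife standard errors and the |Z| ≥ 3 decision rule.
* **Archaic-introgression HMM** — a reference-free two-state Poisson HMM
  on binned counts of variants private to a focal individual relative to
  an outgroup panel, with Baum–Welch training, posterior decoding at a
  0.98 cutoff, cross-individual overlap, and a rough emission-rate
  divergence readout t = λ/(μ·B).
* **Neutral rate** — Nei–Gojobori (1986) synonymous distances and
  r = Ks/2t with generation-time scaling.
* **Synthetic cohorts** — an msprime-based generator reproducing the
  study demography (East/WC split 84.4 ka, WCa/WCb split 6.7 ka with
  migration, 10% ghost pulse from a 3 Ma donor, μ = 8.415×10⁻⁹ per
  generation, g = 8.5 yr, 1 cM/Mb) with exact per-haplotype truth tracts
  and hard-sweep injection, so every stage is verifiable with no data
  download.

## Worked example

Simulate a cohort with a ghost pulse, call introgressed segments for one
East individual, and contrast divergence inside and outside the calls:

```python
from guenonscan.synthetic_data import DemographyConfig, simulate_cohort
from guenonscan.archaic_hmm import build_observations, train_hmm, decode_segments
from guenonscan.scan_pipeline import dxy_introgression_contrast

cohort = simulate_cohort(DemographyConfig(), n_windows=200, window_bp=50_000, seed=11)
track = build_observations(cohort.haps, cohort.popmap, "East_1",
                           ("WCa", "WCb"), cohort.callable_mask)
params, loglik = train_hmm(track, seed=0)
segments, posterior = decode_segments(track, params, pp_cutoff=0.98)
print(f"lambda_archaic={params.lam_archaic:.2f} "
      f"lambda_nonarchaic={params.lam_nonarchaic:.2f}")
print(f"segments={len(segments)} called_mb={sum(s.length_bp for s in segments)/1e6:.2f}")
res = dxy_introgression_contrast(cohort.haps, cohort.popmap, segments,
                                 cohort.callable_mask, seed=0)
print(f"dxy fold = {res['fold']:.2f}")
```

Output (seed 11):

```
lambda_archaic=6.94 lambda_nonarchaic=0.47
segments=173 called_mb=1.96
dxy fold = 1.47
```

The archaic state emits ~15× more private variants per kilobase than the
background state — the signature of tracts from a deeply diverged donor —
and the called segments cover ≈ 2 Mb of the 10 Mb genome per individual,
consistent with the simulated 10% pulse. Divergence between East and WC
inside the called tracts is ~1.5× the genome background in this single-
individual call set (about 2× when restricted to segments shared across
individuals, as `scripts/acceptance.py` reports) — the same contrast that
distinguishes true introgressed regions from random ones in real cohorts.

The same pipeline runs from the shell:

```bash
guenonscan simulate --scenario full --seed 7 --out fixture/
guenonscan dstat fixture/cohort.vcf fixture/popmap.tsv \
    --p1 WCa --p2 WCb --p3 East --out Outgroup
guenonscan hmm fixture/cohort.vcf fixture/popmap.tsv \
    --focal East_1 --callable fixture/callable.bed --out segments.bed
```

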