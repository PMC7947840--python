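# Methods

`guenonscan` implements the population-genomic core of a small-cohort
primate resequencing analysis: windowed diversity and differentiation
statistics, a haplotype-based cross-population sweep scan, four-taxon
admixture tests, a reference-free archaic-introgression HMM, a neutral
mutation-rate estimator, and a coalescent synthetic-data generator that
makes every stage testable without any real cohort.

## Data model and conventions

All statistics consume a `HaplotypeSet`: a phased 0/1 allele matrix with
two rows per diploid sample and one column per biallelic SNP. Internal
coordinates are 0-based half-open; VCF (1-based) and BED (0-based) are
converted only at the I/O boundary, so interchange with both standards is
bit-exact. Missing alleles are excluded site-wise from allele counts; no
imputation is performed, matching a filter-then-count pipeline. Genotypes
with one missing allele are treated as missing.

Site filters follow a conservative short-read calling pipeline: SNPs
within 6 bp of an indel call are removed (distance <= radius; the radius
is configurable because "within about 6 bp" admits either reading), QUAL
< 40 removed, non-biallelic records removed, and sites genotyped in fewer
than 95% of samples removed. A removed site is charged to the first rule
it fails so the per-rule counts partition the input — a property the test
suite asserts. "Consensus quality" is mapped to the VCF QUAL field, the
only portable analogue across callers.

Near-duplicate samples are screened by pairwise identity-by-state
(1 - |dosage difference|/2 averaged over co-called sites); the default
flagging cutoff is 0.45, chosen above the expected unrelated-pair plateau
for a structured cohort where one member of a pair at 0.4988 would be
excluded.

## Windowed statistics

* **pi** — per window, the sum over SNPs of `2 p (1-p) n/(n-1)` (n =
  called haplotypes) divided by window length (or callable bp under a
  mask). This equals the mean pairwise haplotype difference per bp, and
  the suite asserts that equivalence exactly on random instances.
* **dxy** — per region, the sum of `pA(1-pB) + pB(1-pA)` divided by
  length; equals the mean between-population pair difference.
* **Fst** — the two-population Weir & Cockerham (1984) variance-components
  estimator with observed heterozygosity, combined across sites as a
  ratio of sums (sum a / sum (a+b+c)) rather than a mean of per-site
  ratios; the ratio-of-sums is what windowed Fst tools report and is less
  biased at low per-site information. Windows with no informative site
  are flagged undefined and excluded from quantile ranking. Negative
  window estimates are clamped to 0 before any transform.
* **PBS** — `T = -ln(1 - Fst)` per pair (natural log; the PBS literature
  uses ln), with Fst capped at 0.995 so fixed differences give a large
  finite branch length rather than an infinity; `PBS_a =
  (T_ab + T_ac - T_bc)/2`, cyclically for the other branches. The branch
  sum `(T_ab+T_ac+T_bc)/2` is conserved and asserted to 1e-12.
* Windows need >= 10 SNPs (configurable) to enter quantile ranking, and
  trailing partial windows are excluded from ranking, avoiding
  length-biased extremes.

Empirical thresholds use nearest-rank quantiles: the upper-q threshold is
the ceil(qN)-th largest value, so at least a fraction q of windows sit at
or above it. This makes "top 1%" well defined for any N.

## XP-EHH

EHH here is the pooled, allele-agnostic form used by cross-population
scans: the probability that two randomly drawn haplotypes of a population
are identical at all SNPs from the core (exclusive) to the evaluation
point. iHH integrates EHH over genetic distance (trapezoid, constant
1 cM/Mb map by default) in both directions; integration stops where the
EHH of the two populations pooled decays below 0.05 (the originating
implementation's default) or at 1 Mb. Cores need pooled MAF >= 0.05. The
raw score ln(iHH_A/iHH_B) is normalized genome-wide by subtracting the
mean and dividing by the population (n) standard deviation — the n vs n-1
choice is irrelevant at genome scale but fixed for determinism — and then
averaged per window.

The implementation sorts haplotypes lexicographically along the walk once
per core and derives all prefix homozygosities from adjacent
first-difference positions; a chunked evaluation exploits the fast decay
of EHH under neutrality. Results are identical to the direct
pair-counting definition, which the suite asserts on toys.

## D-statistics

Patterson's D uses frequency-based pattern mass per polarized site:
`ABBA = (1-p1) p2 p3`, `BABA = p1 (1-p2) p3`, derived-allele frequencies
polarized by the outgroup group (sites with a polymorphic outgroup are
skipped; with single-sample groups this reduces exactly to count-based
D). Standard errors come from a weighted delete-one block jackknife
(Busing's formula) over contiguous blocks with weights proportional to
informative-site counts; |Z| >= 3 flags significance. The default block
is 5 Mb for real-scale data; desk-scale synthetic genomes use smaller
blocks, which is an analysis-resolution choice, not part of the
statistic. Sites with missing data in any group are skipped without
frequency rescaling.

## Archaic-introgression HMM

For a focal individual, the genome is tiled into 1-kb bins and the number
of allele copies the individual carries that are absent from an outgroup
panel (here WCa+WCb) is counted per bin. A local background mutation-rate
weight is computed per 100-kb window as outgroup variant density over the
genome-wide mean (floored at 0.05 to keep Poisson means positive), and
bins with callable fraction < 0.5 are masked from training and decoding.

Emissions are Poisson with mean `lambda_state * callable_frac *
rate_weight`. Baum-Welch EM uses scaled forward/backward recursions (no
underflow at any length); the M-step for the rates is the
exposure-weighted ratio `sum(gamma * count) / sum(gamma * exposure)`.
Training restarts from a deterministic spread of initial rate ratios
(archaic rate 2, 4, 8, 16, 32 times the genome mean, with a small seeded
jitter), replacing an unspecified "vary the starting parameters"
protocol; the best-likelihood restart wins, and states are label-swapped
so the archaic state always has the larger rate. Segments are maximal
runs of bins with posterior probability of the archaic state >= 0.98
(configurable; segments below a minimum length can be dropped, e.g.
10 kb for high-confidence analyses). Cross-individual overlap is plain
half-open interval intersection.

The divergence readout `t = lambda / (mu * bin_bp)` converts a state's
emission rate to years under a constant per-year mutation rate. It is
reported for both states and labelled rough: it ignores gene flow,
population-size change and the coalescent background, and therefore
overestimates split times by roughly the ancestral coalescent time. Which
state's rate (and what branch factor) the source analysis used for its
printed divergence is not stated, so neither state is privileged.

## Ks and the neutral rate

`ks_ng86` implements Nei-Gojobori (1986): per-codon synonymous-site
fractions from the standard code (mutations to stop codons count as
nonsynonymous for site counting, so S + N = 3 per codon), observed
differences averaged over all mutational pathways excluding those passing
through stops, and the Jukes-Cantor correction
`Ks = -3/4 ln(1 - 4 pS / 3)`. NG86 is the canonical closed form for a
synonymous distance and approximates counting-method estimates from
codeml-style tools to well within the downstream rounding of r.
`neutral_rate` applies `r = Ks / (2 t)` and scales by generation time;
the divergence time t is an explicit argument because no single value is
canonical. With r = 0.99e-9 /bp/yr and g = 8.5 yr the per-generation rate
is 8.415e-9 /bp — the one exactly reproducible worked value, asserted to
machine precision.

## Synthetic cohorts

`DemographyConfig` encodes the study system: East, WCa and WCb ingroup
populations plus an outgroup, with the East/WC split at 84.4 ka, the
WCa/WCb split at 6.7 ka with ongoing symmetric migration (1e-4 per
generation by default), generation time 8.5 yr, per-generation mutation
rate 8.415e-9/bp and 1 cM/Mb recombination. A deep "ghost" lineage
(default divergence 3 Ma) donates a single admixture pulse (default 10%)
into East at 40 ka — after the East/WC split, matching the inferred
ancient origin of the foreign ancestry; the pulse time is not separately
estimated anywhere and only needs to respect pulse < split < donor
ordering. The outgroup split defaults to 3.5 Ma so the donor remains the
outgroup's sister inside the ingroup clade. Effective sizes are not
printed numerically in the source material; defaults (20-40k per branch)
were chosen once to give primate-realistic diversity (theta about 1e-3
per bp) and are fully configurable.

Windows are simulated as independent msprime replicates (free
recombination between windows, 1 cM/Mb within) and concatenated on one
synthetic contig. This is sufficient for every windowed statistic and
keeps runtimes at desk scale; its one limitation is that linkage never
crosses window boundaries, so XP-EHH integration is truncated at window
edges when scanning such cohorts — the scan API exposes exactly that
switch. Ghost ancestry is tracked exactly via a census event one
generation above the pulse: a haplotype segment is a truth tract when its
census-time ancestor sits in the ghost population.

`inject_sweep` creates the hard-sweep signal class by copying one donor
haplotype onto ceil(carrier_frac * n) target haplotypes (defaults: 95%
carriers, mean tract 200 kb with independent exponential endpoints per
side) and sprinkling new private mutations on copied tracts at 1e-5/bp —
the mutation input mu*t of a sweep roughly 10 ka old under the default
rates. It is a star-genealogy approximation, not a forward simulation;
it produces the joint low-pi / high-PBS / high-XP-EHH signature a scan
must detect, but not the precise site-frequency spectrum of a real sweep.

What passing tests on these cohorts do not show: robustness to phasing
error, genotyping error, reference bias, uneven callability, or linked
selection — none of which the generator emulates.

## Numerical and experimental choices

* Forward/backward uses per-bin max-rescaled emissions plus scaling
  coefficients; EM stops when the log-likelihood improves by < 1e-4.
* Degenerate inputs are flagged rather than silently absorbed: undefined
  window Fst, zero-SD normalization, empty quantile input, pS >= 0.75,
  fewer than two jackknife blocks.
* Desk-scale experiment sizes: simulator calibration uses 200
  independent 10-kb windows; HMM recovery uses 50-Mb cohorts (50k 1-kb
  bins); sweep-recovery replicates use 120-window (6-Mb) genomes so the
  nearest-rank 1% tail contains two windows rather than one, which
  removes rank quantization that a genome-scale scan does not have;
  D-statistic replicates use 1.5-Mb genomes with 250-kb jackknife
  blocks.
* All randomness flows from explicit integer seeds; reruns are
  byte-identical, which the suite asserts end to end.

## Known limitations

* The Fst estimator is the two-population form; multi-population trees
  beyond the three-branch PBS contrast are out of scope.
* The HMM's divergence readout is a rough constant-rate transform, not an
  inference of admixture time; transition rates are not converted to
  tract-age estimates.
* NG86 does not model transition/transversion or codon-usage bias; for
  strongly biased genes it underestimates Ks relative to ML methods.
* The sweep injector overwrites haplotypes in place and therefore breaks
  coalescent exchangeability within the swept window; statistics other
  than the scan trio should not be interpreted there.
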