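# Methods

`bsaseq` quantifies DNA methylation differences between two populations from
targeted bisulfite amplicon sequencing, and ships a synthetic-cohort
generator with known truth so the whole chain — reads to calls to posterior
inference — can be validated without any external data. The motivating use
case is comparing stress-gene promoter methylation between wildlife
populations with different anthropogenic exposure (e.g. the endangered
Southern Resident vs the Northern Resident killer whales), where the assay
targets a handful of promoter amplicons (*ACTB* as control, *BDNF*, *CRF*,
*NR3C1*) at high per-locus read depth.

## Reference model

A locus is a promoter amplicon with a transcription start site (TSS) anchor.
CpG sites are labelled by the cytosine of the CG dinucleotide on the top
strand and by a TSS-relative coordinate: the base immediately 5' of the TSS
is −1 (no position 0; downstream bases would be +1, +2, ..., supported for
generality although promoter assays only use negative labels).

Bisulfite treatment converts unmethylated cytosine to uracil (read as T)
while 5-methylcytosine stays C; because conversion acts per strand, the two
strands of a treated molecule are no longer complementary. The package
therefore carries two fully-converted strand references per locus (OT =
original top, OB = original bottom; every C → T) and annotates where CpG
cytosines sat. The bottom-strand cytosine of the CpG at top index *i* sits
at OB index *len − i − 2*; OB evidence maps back to the same top-strand
site label. Primer validation checks exact presence of the pair on a
converted strand and flags any primer footprint overlapping a CpG (such
primers bias amplification by methylation state).

Degenerate inputs: lowercase (soft-masked) references are uppercased on
load; ambiguity codes are rejected with the offending position, since
amplicon references are small and should be clean.

## Read processing

Four stages, re-implemented as explicit rules so they are testable against
oracles rather than external binaries:

- **Primer demultiplexing** — each forward primer is matched semi-globally
  against the read 5' end (prefix alignment; substitutions and indels cost
  1). A primer is acceptable when its edit distance is at most
  ⌊0.2 × primer length⌋ (error rate configurable); the lowest-distance
  primer wins and is trimmed off; ties leave the read unassigned and
  counted. The floor rule at boundary lengths is a deliberate, documented
  convention. Matching uses edlib's prefix mode; the test oracle is an
  independent full dynamic program.
- **Quality trimming** — leading then trailing bases with Q < 20 are
  removed, then the read is truncated at the start of the first 5-base
  window whose mean quality falls below Q30 (complete windows only,
  scanning 5'→3'). End-trimming is applied before the window scan; the
  window cut does not re-trigger end-trimming, so in rare contrived quality
  profiles the retained read can end on a base just below the end
  threshold — the behaviour matches the stated rule order exactly.
- **Pair merging** — read 2 is reverse-complemented and every overlap
  length ≥ 10 is scored as matches − mismatches; overlaps with mismatch
  density > 0.25 are inadmissible; the best score wins, ties going to the
  longer overlap. Consensus takes the higher-quality base (read 1 on
  quality ties), with quality max(q₁,q₂) at matches and |q₁−q₂| at
  mismatches. Defaults are the published defaults of the overlap-merging
  tools this mirrors, and are configurable.
- **Bisulfite-aware alignment** — trimmed reads are aligned semi-globally
  to both converted strands with scoring match +1, mismatch −1, gap open
  −2, gap extend −1. At reference CpG-cytosine positions both read C
  (methylated) and read T (converted) count as matches; the converse (read
  C over an ordinarily converted position) stays a mismatch — the asymmetry
  that makes the alignment bisulfite-aware. Alignments scoring below
  0.8 × read length are rejected; an exact score tie between strands leaves
  the read unaligned and counted. Implementation detail: a vectorised
  ungapped scan over all offsets is tried first; the affine-gap dynamic
  program runs only when the ungapped optimum shows real homology (score
  > 0) without reaching the acceptance threshold — amplicons are a few
  hundred bases, so no index structure is needed.

## Methylation calling

Percent methylation at a site for an individual is 100 × C/(C+T) over all
covering reads. A/G/N calls at a CpG column carry no bisulfite information
and are excluded from the denominator (not counted as unmethylated); a site
with no informative calls is missing. Read depth for filtering is the number
of aligned reads assigned to the locus for that individual (per-site
informative depth is additionally reported, and a per-site threshold mode is
available as a switch). An individual's values at all sites of a locus are
masked when that depth is below the locus threshold; depth equal to the
threshold passes. Defaults mirror the study the pipeline models: ACTB
10 000, BDNF 20 000, CRF 100, NR3C1 500. For loci whose merged-pair depth is
poor, forward reads whose pairs failed to merge can be aligned individually
and pooled into the pileup (the salvage rule, enabled per locus; default
NR3C1). Incomplete-conversion read filtering (dropping reads with many
retained non-CpG Cs) is implemented but off by default. No per-base quality
floor is applied at CpG columns by default; one is available.

## Synthetic cohort

The generator emulates the matched two-population design: 17 focal (SRKW)
individuals, each matched by one or two comparison (NRKW) individuals of
the same sex and similar age (Gaussian jitter, SD 1.5 y; ages uniform on
3–50 y), 30 comparison individuals in total. Truth for individual *i* at
site *s* is

    p_is = clamp01( (δ_s + η_{pop(i),s} + β_age·age_i + β_sex(sex_i) + u_i) / 100 ),
    u_i ~ Normal(0, σ_ind)

with defaults: per-site baselines δ_s cycling through 35–65%,
population×site effects η zero everywhere except +20 pp and −20 pp at CRF
−101 and −95 (the hyper-/hypomethylation pattern the assay is meant to
detect), β_age = β_sex = 0, σ_ind = 5 pp. Per-(individual, locus) read
depth is lognormal (σ_log = 0.5) around per-locus means of 15 000 / 25 000 /
300 / 800 — chosen to straddle the default depth thresholds so threshold
filtering is actually exercised.

Reads are simulated per molecule: each CpG cytosine survives conversion
with probability p_is; each non-CpG cytosine survives with the conversion
failure probability (default 1%, a typical bisulfite failure rate);
per-base substitution errors at 0.1% (Illumina-like); 250+250 bp pairs over
300 bp amplicons, so pairs overlap and merging is always geometrically
possible. A flag generates non-overlapping pairs to exercise the salvage
path. Primer bases are written verbatim over the read starts — they come
from the synthetic oligo, not the converted molecule. Qualities are a
high-Q core (Q38) with a short lower-Q 3' tail (Q25) and ±2 jitter.
Methylation is independent per read and per site: the downstream statistic
is a per-site proportion, so within-molecule haplotype correlation would
not change anything it measures. One global seed drives named
per-individual/per-locus substreams, so any slice is reproducible in
isolation and FASTQ output is byte-identical across runs.

A counts-level route samples per-site (C, T, other) counts directly from
the same emission probabilities (multinomial at the lognormal depth),
equivalent in distribution to error-free-geometry read simulation and far
cheaper for deep designs; deep-coverage model validation uses it.

What the generator does not model: PCR amplification bias and chimeras,
index hopping, quality miscalibration, C/T SNPs (which masquerade as
methylation calls), and molecule-level methylation haplotypes. Passing
tests therefore demonstrate the pipeline's correctness and the model's
statistical behaviour under these idealisations, not robustness to
artefacts real libraries can contain.

## Hierarchical model

One observation per non-missing (individual, site) cell:

    y ~ Normal(μ, σ_pop),
    μ = δ_s + γ_p + η_{p,s} + β_age·z_age + β_sex(sex) + u_i,
    u_i ~ Normal(0, σ_ind)

on the percent scale (no logit, no truncation — the predicted variable is
percent methylation directly). Index coding is used for site, population,
sex and the site×population interaction; the individual enters as a
zero-mean random effect (a fixed-effect coding would be unidentifiable
jointly with population). Age is standardized by the contributing cohort's
mean and sample SD (n−1). Residual SD is population-specific. Other
pairwise interactions are deliberately excluded. Priors (percent scale):
δ_s ~ N(50, 25), γ_p ~ N(0, 10), η ~ N(0, 10), β_age ~ N(0, 10),
β_sex ~ N(0, 10), σ_ind ~ HalfNormal(10), σ_pop ~ HalfNormal(15). The
location split among δ/γ/η/β_sex is redundant and only softly identified by
the priors; all reporting is through the identified population contrast

    Δ_s = (γ_F + η_{F,s}) − (γ_R + η_{R,s})

(focal minus reference; positive = hypermethylation in the focal
population, default focal SRKW). Contrasts marginalise the individual
effects, which cancel in expectation. Each Δ_s is summarised by its
posterior mean, the 95% highest density interval (HDI: the shortest
contiguous interval over the sorted draws containing ⌈0.95·n⌉ of them; ties
on width break toward the lower start), and a classification:
hypermethylated if the HDI lies entirely above 0, hypomethylated if
entirely below, no_difference otherwise.

**Sampler.** The model is linear-Gaussian given the three scale parameters,
so sampling is blocked Gibbs: all location coefficients are drawn jointly
from their exact multivariate-normal full conditional (one Cholesky of the
~130×130 posterior precision per sweep; the per-population Gram matrices
are precomputed, so each sweep is O(P²) plus the factorisation), and
σ_ind, σ_pop are updated by univariate slice sampling on log σ
(stepping-out width 0.7). The joint coefficient draw removes the posterior
correlations that make single-site Gibbs slow, so mixing is excellent
(bulk ESS typically near the number of kept draws). Defaults: 4 chains ×
(1000 warmup + 1000 kept), overdispersed random inits for the scales.
Convergence contract: split-R̂ < 1.01 and bulk ESS > 400 (computed with
arviz) for every reported contrast; a fit that misses the contract is
flagged and warned about but still returns contrasts. Replicate-heavy
validation (the control-gene and calibration checks) uses reduced settings
(2 chains, 500–750 kept draws) to keep total runtime in minutes; the
single-fit checks use the full defaults.

## Validation and what it shows

- Counting, trimming, demultiplexing and HDI computation are checked
  against exhaustive independent oracles (brute-force column tally, full
  edit-distance dynamic program, every-window scan, all-windows HDI
  search) — exact agreement required.
- Error-free end-to-end runs at depth 1000 must land within 3 binomial
  standard errors of truth at ≥99% of cells and exactly at 0/100 where
  truth is 0 or 1.
- Under the matched 17+30 design with the planted ±20 pp CRF effects, the
  fitted model must flag exactly those two sites with the correct signs
  and leave ≥21 of the 23 null sites covering zero.
- Calibration: fitting data drawn from the model's own prior predictive,
  the 95% HDI for Δ_s covers truth at ≈95% (accepted band 89–99%) over 100
  reduced replicates (5 sites, 10+10 individuals, direct truth-level
  matrices).

Two statistical caveats the validation surfaced, documented rather than
tuned away. First, with σ_ind = 5 pp the chance imbalance of individual
effects between cohorts of 17 and 30 has SD 5·√(1/17+1/30) ≈ 1.5 pp; it is
statistically indistinguishable from a population effect and therefore
feeds Δ_s. Roughly 3% of replicate cohorts draw an imbalance large enough
(≳3.4 pp) to push every control-gene HDI past zero at once — a real
property of a 47-individual two-population design, visible in the
control-gene replicate check. Second, the posterior mean of a truly null
covariate (age, sex), measured in units of its posterior SD, is itself
approximately standard normal across cohort realizations (the model is
calibrated, and the chance age/sex confound in a finite cohort is real), so
"centres near zero" holds in distribution, not for every single cohort.

## Limitations

The Normal likelihood on the percent scale can place posterior mass outside
[0, 100] near the boundaries; for the mid-range methylation levels and
effect sizes this assay targets that is immaterial, but strongly
boundary-concentrated sites would warrant a Beta or logit-normal variant
(out of scope here). Depth thresholds are per locus, matching the study
design the pipeline models; per-site thresholds are available but not the
default. The aligner is deliberately direct (no FM-index) and unsuitable
for genome-scale data. No SNP-aware calling: a C/T polymorphism at a CpG
looks like methylation.
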