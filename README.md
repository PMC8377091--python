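# bsaseq

Bisulfite amplicon sequencing analysis: from paired-end reads to per-CpG
percent methylation to Bayesian per-site population contrasts.

Targeted bisulfite sequencing is a practical way to ask whether two
populations differ in DNA methylation at candidate genes — for example,
stress-response promoters (*BDNF*, *CRF*, *NR3C1*, with *ACTB* as control)
in wildlife populations with different anthropogenic exposure, where a skin
biopsy is all the material there is. `bsaseq` implements that analysis as a
tested, reusable pipeline:

1. **Reference model** — promoter amplicons with TSS-relative CpG
   coordinates (−101 means 101 bp upstream of the TSS), in-silico bisulfite
   conversion, converted OT/OB strand references, primer validation.
2. **Read processing** — error-tolerant 5' primer demultiplexing (edit
   distance ≤ ⌊0.2·primer length⌋), Q20 end trimming plus a 5-base
   sliding-window mean-Q30 cut, overlap merging of pairs, and
   bisulfite-aware semi-global alignment (read C *or* T both match at
   reference CpG cytosines).
3. **Methylation calling** — per individual and CpG site,
   percent = 100·C/(C+T) over covering reads; per-locus minimum-depth
   filtering (defaults ACTB 10 000, BDNF 20 000, CRF 100, NR3C1 500) and an
   unpaired-forward-read salvage rule for poorly merging loci.
4. **Differential model** — a Bayesian hierarchical regression on the
   percent scale,

       y ~ Normal(δ_s + γ_p + η_{p,s} + β_age·z_age + β_sex + u_i,  σ_p),
       u_i ~ Normal(0, σ_ind),

   fitted by a blocked Gibbs sampler (joint conjugate draw of all location
   terms, slice updates for the scales), with split-R̂/ESS convergence
   checks. Reported per site: the posterior population difference
   Δ_s = (γ_F+η_{F,s}) − (γ_R+η_{R,s}), its 95% highest density interval,
   and a classification (hypermethylated / hypomethylated / no_difference
   according to whether the HDI excludes zero).
5. **Synthetic cohort** — a first-class simulator of the matched
   two-population design (17 + 30 individuals paired by sex and age, 25
   CpG sites over 4 loci, lognormal per-locus depths, configurable
   conversion failure and sequencing error) with a written truth table, so
   every stage is testable end to end with no external data.

## Worked example

Run the full synthetic pipeline — simulate reads, process, call, fit,
contrast — in a few lines:

```python
from bsaseq.simulate import SimulationConfig, simulate_matrix_counts
from bsaseq.calling import apply_depth_thresholds
from bsaseq.model import MCMCSettings, build_design, contrast_table, fit_model

cfg = SimulationConfig.default(seed=3)          # 17+30 whales, 25 CpG sites,
                                                # +20/−20 pp planted at CRF −101/−95
inds, truth, matrix = simulate_matrix_counts(cfg)
matrix = apply_depth_thresholds(
    matrix, {"ACTB": 10000, "BDNF": 20000, "CRF": 100, "NR3C1": 500}
)
spec = build_design(matrix, inds, mcmc=MCMCSettings(chains=4, seed=7))
draws = fit_model(spec)
print(contrast_table(draws).to_string(index=False))
```

Output (abridged — 25 rows, one per site):

```
      site  mean_delta  hdi_low  hdi_high   classification  rhat  ess_bulk
 ACTB:-250        1.57    -1.82      5.11    no_difference  1.00   4207.07
       ...
  CRF:-101       21.22    17.87     24.44  hypermethylated  1.00   3998.89
   CRF:-95      -17.88   -21.22    -14.64   hypomethylated  1.00   4056.54
       ...
 NR3C1:-85        1.51    -2.00      4.82    no_difference  1.00   3976.86
```

`mean_delta` is the posterior mean difference in percent methylation
(focal SRKW minus reference NRKW) at each TSS-relative CpG position;
`hdi_low`/`hdi_high` bound the 95% highest density interval. Here the two
planted effects are recovered with the right signs and tight HDIs
(+21.2 pp at CRF −101, −17.9 pp at CRF −95), all 23 null sites' HDIs cover
zero, and the diagnostics meet the convergence contract (R̂ < 1.01,
bulk ESS > 400).

The read-level route is available as a CLI for shell use:

```sh
bsaseq run-all --seed 7 --out runs/demo      # simulate → process → call → fit → contrast
bsaseq simulate --seed 7 --out runs/inputs   # or stage by stage
```

Each stage reads and writes plain FASTQ/TSV (optional SAM), so any stage
can be cross-validated against external tools.

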