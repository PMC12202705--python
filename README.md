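# melanokit

Tools for the quantitative arguments behind a minimal-mutation model of
melanoma initiation in Cre-lox engineered mice, where oncogenic *Braf* is
activated in melanocytes and rare tumors arise after a long, apparently
stochastic delay. The package implements four bespoke computations as a
tested pipeline, each exercisable on synthetic data it generates itself:

1. **Single-hit incidence kinetics** (`melanokit.kinetics`). If tumors
   initiate at a constant probability λ per unit time after a detection lag
   t₀, tumor-free survival declines as a single exponential,
   S(t) = exp(−λ·max(0, t − t₀)), and the initiation half-time is
   t₁/₂ = ln2 / λ. The package fits right-censored tumor-free survival
   tables either by weighted least squares on the tail of the log
   Kaplan-Meier curve (the "final slope of the logarithmic plot") or by a
   censored shifted-exponential maximum-likelihood fit with the lag fixed
   or profiled.
2. **loxP-based tumor purity** (`melanokit.loxp`). Unrecombined cells carry
   two loxP sites in distinct genomic contexts; recombined (tumor-lineage)
   cells carry one fused junction. Reads containing the exact 34-bp loxP
   core are classified by their flanking context into unrecombined-5′ (U5),
   unrecombined-3′ (U3) and recombined (R) junctions, and the recombined-cell
   fraction — the tumor-derived DNA fraction φ — is estimated as
   ρ = R / (R + (U5 + U3)/2), with a multinomial bootstrap CI.
3. **Mutation-detection power** (`melanokit.power`). A clonal heterozygous
   mutation in a sample of purity φ is expected on a fraction f = φ/2 of
   reads; with coverage C the number of supporting reads is Binomial(C, f)
   and the probability of missing the mutation entirely is (1 − f)^C
   (generalized to a binomial tail for callers requiring m ≥ 1 reads).
4. **Membership scores for gene signatures** (`melanokit.scoring`). UMI
   counts x_gc are converted to analytic Pearson residuals
   r = (x − μ)/√(μ + c²μ²) with μ_gc = (gene total × cell total)/grand total,
   where c is a per-dataset biological coefficient of variation
   (overdispersion θ = 1/c²); residuals are clipped at ±√(n cells),
   z-scored per gene, and a cell's score for a signature is the mean z over
   the signature's genes. Cluster-centroid Euclidean distances in a
   low-dimensional embedding (e.g. top 10 PCs) are computed alongside.

`melanokit.synthetic_data` provides seeded generators for all three input
kinds — censored exponential cohorts, loxP junction read libraries at a
known cell-fraction mix, and negative-binomial count matrices with planted
signatures — each with a ground-truth record that makes the dataset its own
oracle.

## Worked example

Simulate a 200-mouse cohort with a 33-week initiation half-time, a 4-week
detection lag and 60 weeks of follow-up, then recover the half-time:

```sh
$ melanokit simulate cohort --n-subjects 200 --half-time 33 --lag 4 \
      --followup 60 --seed 1 --out demo_cohort
$ melanokit fit-kinetics --input demo_cohort/cohort.csv \
      --method shifted-exp-mle --lag profile --out demo_fit
half-time 34.01 weeks (lambda 0.02038/week, 139 events, shifted-exp-mle)
```

The fit report (`demo_fit/single_hit_fit.json`) gives
λ = 0.0204/week ± 0.0017, t₁/₂ = 34.0 weeks with 95% CI [28.8, 40.2], and a
profiled lag of 4.0 weeks — the generating values (33, 4) are recovered
within sampling error from 139 observed events.

Estimate tumor purity from an error-free synthetic junction library with a
true recombined-cell fraction of 0.36:

```sh
$ melanokit simulate loxp --rho 0.36 --n-cells 90 --seed 7 --out demo_lib
$ melanokit estimate-purity --reads demo_lib/reads.fastq \
      --loxp-config demo_lib/allele.json --out demo_purity
rho = 0.4222 [0.3294, 0.5053] from 142 informative reads
```

With ~140 informative reads the point estimate carries a ±0.08 CI, which is
why downstream power statements use the purity as given. The corresponding
miss probability for a clonal heterozygous mutation at 40X:

```sh
$ melanokit power --coverage 40 --tumor-fraction 0.19
{
 "allele_fraction": 0.095,
 "p_miss": 0.018447739961905508,
 "p_miss_percent": 1.8447739961905507,
 "p_miss_percent_2sf": 1.8,
 ...
}
```

i.e. even a 19%-pure tumor leaves under a 2% chance of a clonal driver
mutation escaping detection at 40X coverage.

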