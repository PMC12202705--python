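# Methods

## Single-hit incidence model

Tumor-free survival is modeled as a shifted exponential: a subject remains
tumor-free until t₀ + E, with E ~ Exponential(λ). λ (per week) is the
constant per-unit-time initiation probability, t₀ ≥ 0 a detection lag (the
time for an initiated tumor to reach detectable size), and
t₁/₂ = ln2/λ the initiation half-time. Every fit object enforces
t₁/₂ · λ = ln2 exactly; the fit is equivariant under rescaling time.

Two estimators:

- **log-linear-tail** (default). The Kaplan-Meier curve is computed with
  lifelines; log S at the event-time steps from the first observed event
  onward (the pre-lag region carries no slope information) is regressed on
  time by weighted least squares with the number at risk as weights, which
  stabilizes the sparse tail. Zero-survival steps are excluded (log 0).
  The lag is read off where the fitted line crosses S = 1 (intercept/λ,
  floored at 0): a graphical lag estimate consistent with
  `predict_survival`. At least 3 distinct event times are required; a
  non-positive slope raises a `FitError` with diagnostics. The regression
  SE is reported but is approximate — KM steps are serially correlated.
- **shifted-exp-mle**. For fixed t₀ the censored-likelihood MLE is
  λ̂ = D / Σᵢ max(0, tᵢ − t₀) (events over time at risk beyond the lag),
  with SE(λ̂) = λ̂/√D and Wald intervals built on the log scale so they stay
  positive. t₀ may be fixed (default: the first event time), supplied, or
  profiled on a 0.5-week grid up to the first event time.

For parameter-recovery claims (median accuracy and 95%-interval coverage on
simulated cohorts) the MLE is the estimator of record, chosen because its
uncertainty theory is exact for the generating model; the log-linear fit is
the default interface because it mirrors how half-times are extracted from
logarithmic survival plots, and its point estimates track the MLE closely.

Cohort simulations for the recovery checks use n = 200 subjects, no lag,
60 weeks of administrative follow-up and 50 replicates per half-time
(6, 15, 33 weeks) — study-plausible cohort sizes and horizon; only
administrative censoring is modeled (no random dropout).

## loxP junction classification and purity

The classifier scans each read (both strands by default) for an exact match
to the 34-bp loxP core, then compares k bases of context on each side
(default k = 3) to the configured flank sequences: (A,B) → U5, (C,D) → U3,
(A,D) → recombined; any other combination, or fewer than k bases of context,
is ambiguous. A read contributes at most one count per class. Core matching
is exact; an opt-in `max_flank_mismatches` tolerates substitutions in the
flanks only. The source protocol states the context requirement as "at
least two nucleotides" in one place and "at least three bases" in another;
the default is the stricter k = 3 and the parameter is exposed.

Purity: ρ = R / (R + (U5 + U3)/2). The halving reflects the 2:1 loxP
site-count asymmetry — each unrecombined cell carries two sites, each
recombined cell one — and equals R over (R + the average of U5 and U3).
The CI is a percentile bootstrap (default 2000 replicates) over the
multinomial of informative reads; assumption-light, since no parametric CI
was specified for this estimator. Ambiguous reads are excluded from the
denominator. With error-free synthetic libraries the estimate reduces to
the recombined-cell binomial proportion, which is how round-trip tests
bound its sampling error.

## Mutation-detection power

f = φ · z with zygosity factor z (0.5 heterozygous default, 1.0 homozygous);
p_miss = P(X < m), X ~ Binomial(C, f). The single-supporting-read criterion
m = 1 — p_miss = (1 − f)^C — is the canonical surface; m > 1 is provided as
a clearly labeled extension for callers that require multiple supporting
reads. Coverage is treated as fixed, not Poisson-distributed. Reported
percentages carry a 2-significant-figure convenience rounding alongside the
raw double.

## Membership scores

The NB null for UMI counts sets Var(x) = μ + c²μ², with c the biological
coefficient of variation; this maps to the usual overdispersion as
θ = 1/c², the interpretation this module adopts for the CV parameter.
Expected counts are the product of marginals (μ_gc = row·col/grand),
residuals r = (x − μ)/√(μ + μ²/θ) are clipped at ±√(n cells) following the
analytic-Pearson-residual recommendation, with no further correction
applied. Genes with zero totals are removed with a warning. Residuals are
z-scored per gene using the sample (n−1) SD — fixed by convention and
tested — and zero-variance genes are dropped. A cell's membership score for
a signature is the unweighted mean of z over the signature genes present in
the matrix; identifiers match case-insensitively, an optional symbol map
translates between naming schemes (e.g. human → mouse), and missing genes
are reported, never imputed. Datasets from different genotypes are scored
separately, each with its own empirically determined c (0.55, 0.65, 0.65
for the three tumor genotypes in the motivating study); a moment-based
estimator fitting Var = μ + c²μ² across genes is provided as a non-canonical
convenience for choosing c. A weighted variant (weighting genes by
differential expression) is described elsewhere in the motivating work but
no weighting scheme is defined; this module implements the plain unweighted
average.

Cluster-centroid distances: per-cluster means of the first d embedding
coordinates (d = 10 for PC embeddings, 30 for integrated embeddings in the
motivating study; d is a parameter here), pairwise Euclidean; empty
clusters are excluded with a warning.

## Synthetic-data generators

All generators draw from a single `numpy.random.default_rng(seed)` per
dataset; seeds are recorded in truth sidecars and run manifests, and equal
seeds give byte-identical files.

- **Cohorts**: times = lag + Exponential(ln2/t₁/₂), administratively
  censored at follow-up. Emulates waiting-time structure only — no
  per-animal tumor multiplicity, no competing risks.
- **loxP libraries**: Binomial(n_cells, ρ) recombined cells; each
  unrecombined cell emits one U5 and one U3 read, each recombined cell one
  R read; reads are core-centered, strand-randomized, with independent
  per-base substitution errors (no indels — the classifier requires an
  exact core, so substitutions suffice to probe robustness). Qualities are
  constant (the classifier ignores them). Flanks are random distinct
  20-mers by default since the engineered allele's context is
  locus-specific. Real fragmentation places the core at variable offsets;
  centering is a simplification that does not affect class frequencies.
- **Count matrices**: per-type expression profiles apply planted log2 fold
  changes to a lognormal(0,1) baseline and are renormalized so every cell's
  expected depth equals `depth_per_cell` (default 1000 counts — a modest
  droplet-style depth); counts are NB(μ, θ = 1/c²) with default c = 0.55.
  The renormalization means a planted log2FC of 1 yields a mean ratio of
  2× a common attenuation factor, exactly as in a fixed-depth sequencing
  experiment; truth records the per-type means so tests can assert this
  exactly. Not emulated: doublets, ambient RNA, batch effects, gene-gene
  correlation. Passing tests therefore demonstrate correctness of the
  scoring arithmetic and calibration under the assumed noise model, not
  robustness to real-data artifacts.

## Numerical and design notes

- Ties in event times follow the standard product-limit convention
  (simultaneous events share a KM step).
- The purity bootstrap and all stochastic estimators accept explicit seeds;
  CLI invocations write a `manifest.json` with parameter hashes, input
  digests and seeds so deterministic stages can be verified byte-for-byte.
- Structured CLI configuration files are JSON (one object of spec fields),
  with command-line options taking precedence.
- Problem sizes in the test suite (e.g. 500 genes × 2000 cells for
  calibration, 50 replicates × 200 subjects for recovery) are chosen as the
  smallest sizes at which the distributional claims are statistically
  sharp; they run in seconds.
- Optional plotting (log-survival curves, UMAP overlays) is out of scope;
  outputs are tabular/JSON.

## Known limitations

- The log-linear tail fit's SE underestimates sampling variability on
  heavily censored data; use the MLE when intervals matter.
- The CV moment estimator is biased low when expression means are small
  relative to 1/c²; it is a convenience, not the canonical procedure.
- Purity from junction reads assumes equal amplification/mappability of the
  three junction classes; real WGS may violate this mildly.
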