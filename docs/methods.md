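# Methods

## Problem and model

Bulk expression signatures for prognosis are notoriously fragile: a single
biopsy samples one region of a spatially heterogeneous tumor, so any gene
whose expression varies strongly *within* a tumor contributes sampling
noise rather than signal. Given multi-region RNA-seq (several samples per
tumor), per-gene variability can be split into an **intratumor** component
(among regions of one tumor) and an **intertumor** component (among
patients). Genes with high intertumor but low intratumor heterogeneity —
"Q4" genes, typically expressed from clonal copy-number events — carry
patient-level signal that a single biopsy measures reliably, and are the
raw material for a reproducible risk score.

All analysis operates on log2-scaled expression. Linear-scale input
(counts, FPKM or RSEM) is first library-size-normalized: each sample
column is rescaled so its total equals the cohort-median total, then
transformed by `log2(x + 1)`. The pseudocount keeps zeros at zero; whether
to re-normalize already-normalized FPKM/RSEM input is a configuration
choice (`scale_tag`), since only the relative column totals are affected.

### Heterogeneity scores

For gene *g*:

- **intratumor score** = median over patients of the sample SD (n−1
  denominator) of *g*'s log2 expression across that patient's regions;
- **intertumor score** = mean over B = 100 resampling iterations of the
  cross-patient SD of a single-region cohort formed by drawing one region
  per patient uniformly at random. One region draw per iteration is shared
  by all genes, preserving cross-gene correlation; the estimator's exact
  expectation (enumerating all R^P combinations) is implemented for small
  cohorts and used to validate the Monte-Carlo version.

**Q4 call**: intertumor score strictly above the gene-set median AND
intratumor score at or below the gene-set median. The quadrant cut is the
only parameter-free choice consistent with a Q4 fraction below 25%; the
universe over which medians are taken is the caller's choice (all genes by
default).

### Clustering concordance coefficient

Per gene, all region samples are clustered on that gene's expression alone
(one-dimensional k-means, Lloyd's algorithm, 10 restarts: first restart
from evenly spaced quantiles, the rest k-means++; uniform random starts
measurably miss the global optimum). For each k in 2..min(26, n_patients)
the concordance is the fraction of patients whose regions all share a
cluster; the coefficient is the mean over k. Genes with coefficient
strictly greater than 0.2 pass the filter. When k exceeds the number of
distinct values, all distinct values become centers and surplus clusters
stay empty (logged). An exact dynamic-programming 1-D k-means serves as
the test oracle; the heuristic matches it on ≥ 95% of (gene, k) pairs on
synthetic cohorts. Note the SS-optimal clustering is *not* invariant under
arbitrary monotone transforms of expression (only affine ones); what is
preserved is that optimal clusters are contiguous in sorted order.

### Signature discovery chain

Five steps, in order, on a discovery survival cohort plus a multi-region
cohort: (1) remove the ⌊G/2⌋ genes with lowest median expression in the
discovery cohort; (2) keep genes with univariable Cox Wald p < 0.01;
(3) intersect with Q4 genes; (4) keep concordance coefficient > 0.2;
(5) lasso-Cox at fixed penalty λ = 0.06 and refit the selected genes by
unpenalized multivariable Cox for the final per-gene coefficients cᵢ (the
penalized coefficients are exported alongside). Every step logs its
surviving gene count; a step that empties the set is a hard error naming
the step.

The risk score of a sample is S = Σᵢ cᵢ·xᵢ over signature genes (xᵢ = log2
expression). Cohorts are stratified into score tertiles on their own score
distribution (rank split at the 1/3 and 2/3 boundaries, remainders to the
lower groups, ties broken by stable sample order); evaluation reports
Kaplan–Meier curves and the k-group log-rank test across tertiles plus
univariable and covariate-adjusted Cox models on the continuous score.
Missing signature genes in a validation matrix are a hard error by
default; `impute_missing="mean"` substitutes the per-sample mean log2
expression over available genes, an explicit escape hatch for
cross-platform cohorts.

### Survival machinery

Ordinary Cox fits (univariable, multivariable), Kaplan–Meier estimation
and the log-rank test are delegated to lifelines (Efron tie handling,
Wald p-values, 95% CIs). Two pieces are implemented directly on the
Breslow partial likelihood for speed and control:

- a **vectorized univariable screen**: per-gene Newton iterations run
  simultaneously across all genes via reverse-cumulative risk sums
  (O(n·G) per iteration). With continuous times Breslow and Efron
  coincide; agreement with lifelines is pinned in tests.
- the **L1-penalized fit**: FISTA with backtracking on
  −(1/n)·ℓ(β) + λ‖β‖₁ over unit-SD-standardized predictors (glmnet's
  objective scaling, so λ is comparable to that convention). Convergence
  is declared when the KKT subgradient residual drops below 1e-9
  (max 5000 iterations); λ = 0 reduces to the unpenalized MLE.
  Coefficients are reported on both the standardized and original log2
  scales. An independent coordinate-descent implementation
  (scikit-survival's Coxnet) is the cross-check oracle in tests, and the
  score test at β = 0 reproduces the log-rank statistic exactly on binary
  splits.

### Overlap and CNV statistics

The gene-set overlap test is the one-sided (enrichment) hypergeometric
tail computed with log-space binomial coefficients (`gammaln` +
`logsumexp`), exact below 1e-300. Both tail conventions are returned:
`p` = P(X ≥ k) counts the observed overlap in the tail; `p_phyper` =
P(X > k) is what R's `phyper(k, K, N−K, n, lower.tail=FALSE)` computes.
For the published worked example (N = 7064, K = 948, n = 472, k = 208)
the inclusive tail is 1.42e-65 and the strict tail 2.26e-66; only the
strict tail satisfies the printed bound of 1.19e-65, so the printed value
evidently follows the phyper convention, and the headline number is
reported in that convention. The enrichment ratio is k/(K·n/N).

CNV frequencies are the fraction of samples with a call at or beyond the
amplification/deletion thresholds (defaults ±0.3 for real-valued scores,
compatible with {−1, 0, +1} call matrices). Band-level profiles are
unweighted means of member-gene frequencies; cross-cohort comparison uses
Spearman rank correlation over shared keys.

## Synthetic data generator

The generator emulates the target study design: 26 patients × 3 regions
(superior/lateral/inferior) by default. Gene classes and their log2-scale
SDs (between-patient σ_b, within-patient σ_w):

| class     | fraction | σ_b | σ_w | role |
|-----------|----------|-----|-----|------|
| clonal    | 0.20     | 1.5 | 0.1 | patient-level signal, regionally stable |
| subclonal | 0.20     | 0.1 | 1.5 | region-level noise |
| null      | 0.60     | 0.3 | 0.3 | background biological + technical noise |

Expression of gene g in sample s of patient p is
μ_g + a_{g,p} + e_{g,s}, with a ~ N(0, σ_b²) per patient and
e ~ N(0, σ_w²) per region; μ_g ~ Uniform(2, 10) gives the median-expression
filter signal to act on. The clonal/subclonal SDs place each class at the
intended extreme of the intra/inter quadrant plot; null genes sit between,
so the median splits isolate the planted classes. Twenty prognostic genes
are planted among the *expressed* clonal genes (above-median μ_g), so the
low-expression filter removes noise rather than ground truth.

Survival cohorts are single-region draws (per-sample gene variance
σ_b² + σ_w²) with times from an exponential-baseline Cox model,
hazard λ₀·exp(Σ β_g(x_g − μ_g) + covariate effects); λ₀ = 1/365 per day,
β = ±0.5 per unit log2 for planted genes, covariate effects zero by
default. Censoring is an independent exponential time with rate
λ₀·c/(1−c), giving a censored fraction of exactly c (default 0.3) under
the null. CNV matrices are per-(band, sample) Bernoulli draws shared by
all genes of a band, amplification resolved first on conflicts.

What the generator does **not** emulate: count-level dispersion
(negative-binomial noise), batch/platform effects, gene–gene correlation
beyond the shared patient effect, non-proportional hazards, and informative
censoring. Passing tests therefore demonstrate correctness of the
estimators and the selection chain under a well-specified generative
model, not robustness to those real-data pathologies.

## Problem sizes and numerical choices

The bundled analysis uses 2,000 genes, a 300-sample discovery cohort and a
211-sample validation cohort. Discovery at n ≈ 90 is possible but
fragile under the default effect sizes: the 20 planted genes jointly give
the linear predictor an SD of ≈ 3.4, which acts as heavy unmodeled frailty
in the per-gene marginal screen and can leave no gene at p < 0.01 for some
draws; 300 samples give the screen stable power. Replicate-based checks
use 10–20 seeds.

Other conventions: sample SD uses the n−1 denominator throughout;
duplicate gene ids collapse to the row with highest median; tertile
remainders go to the lower groups; `compare_score_by_group` uses Welch's
t test or the two-sample rank-sum test, unadjusted by default with
optional Benjamini–Hochberg; collinear covariate matrices are rejected
with the offending column named; a patient with fewer than two regions is
rejected by every multi-region operation.

## Known limitations

- Breslow (not Efron) tie handling inside the screen and penalized fit;
  immaterial for continuous times, slightly anti-conservative with heavy
  ties.
- The concordance coefficient is heuristic k-means; a (gene, k) pair can
  land in a local optimum (bounded at < 5% of pairs against the exact DP
  oracle on synthetic data).
- Tertile cutpoints are cohort-specific by design; scores are therefore
  comparable within, not across, cohorts unless coefficients and platform
  match.
- The published cohort-scale gene counts (Q4 fractions, filter-chain
  sizes, cohort hazard ratios) depend on controlled-access datasets and
  are not reproduced here; the worked hypergeometric example is the one
  printed quantity recomputable exactly.
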