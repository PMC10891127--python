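# clonalsig

Clonal gene signature discovery from multi-region tumor expression data.

Prognostic expression signatures built from single biopsies are fragile
because tumors are spatially heterogeneous: a gene that varies among
regions of one tumor contributes sampling noise, not signal. Given
multi-region RNA-seq (several samples per tumor), `clonalsig` scores every
gene's **intratumor** heterogeneity (median across patients of the
regional SD of log2 expression) and **intertumor** heterogeneity (mean
over 100 resamplings of the cross-patient SD of one random region per
patient), keeps the clonally expressed **Q4 genes** (intertumor score
above the median, intratumor score at or below it), and distills them into
a sparse risk score through a five-step chain:

1. drop the 50% of genes with lowest median expression in the discovery
   cohort;
2. keep genes univariably associated with overall survival (Cox p < 0.01);
3. intersect with the Q4 genes of the multi-region cohort;
4. keep genes whose clustering concordance coefficient (mean over
   k = 2..26 of the fraction of patients whose regions co-cluster under
   1-D k-means on that gene) exceeds 0.2;
5. select a core set by lasso-Cox at penalty λ = 0.06 and refit
   unpenalized for the final coefficients.

A sample's risk score is **S = Σᵢ cᵢ·xᵢ** (xᵢ = log2 expression of
signature gene i); cohorts are stratified into score tertiles and
evaluated by Kaplan–Meier/log-rank and by univariable and
covariate-adjusted Cox proportional-hazards models. Companion statistics
cover hypergeometric gene-set overlap (exact, log-space) and copy-number
amplification/deletion frequency profiles with cross-cohort rank
correlation. A seeded synthetic-data generator emulates the full study
design — a multi-region cohort with planted clonal/subclonal/null genes
and Cox-model survival cohorts — so every stage is testable with known
ground truth. See `docs/methods.md` for the model details.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_simulate_cohorts.py --seed 1   # cohorts as TSVs
python analysis/02_heterogeneity_scores.py --seed 1
python analysis/03_discover_signature.py --seed 1
python analysis/04_evaluate_signature.py --seed 1
python analysis/05_overlap_and_cnv.py --seed 1
```

With seed 1 this prints, among other things:

```
2000 genes scored; 479 Q4 (23.95%)
  clonal   : 100.0% flagged Q4
  subclonal:   0.0% flagged Q4
  null     :   6.6% flagged Q4

filter chain: input 2000 -> expression_filter 1000 -> prognostic 23 -> q4 16 -> concordance 15 -> lasso 15
signature: 15 genes, 15 planted prognostic-clonal, 0 false positives

log-rank across tertiles: chi2=126.99 (df=2), p=2.66e-28
univariable score HR: 2.076 (1.822-2.364), p=3.91e-28
multivariable score HR (age/sex/stage/histology adjusted): 2.124 (1.849-2.439), p=1.56e-26
```

Reading: the Q4 quadrant call recovers every planted clonal gene while
letting through only 6.6% of background genes; the filter chain ends in a
15-gene signature consisting entirely of planted prognostic-clonal genes;
and on an independent 211-sample validation cohort the score separates
survival tertiles decisively, with a hazard ratio per score unit of ~2.1
that survives adjustment for age, sex, stage and histology.

The same functionality is scriptable via the `clonalsig` CLI
(`simulate`, `heterogeneity`, `concordance`, `discover`, `score`,
`evaluate`, `overlap`, `cnv-freq`); run `clonalsig --help`.

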