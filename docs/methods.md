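# Methods

`prera` re-implements, as a tested library, the statistical machinery used
to analyse a longitudinal two-group cohort of anti-CCP-positive
individuals: Converters, who developed clinical rheumatoid arthritis (RA)
during follow-up, and matched Nonconverters. Each subject contributes a
baseline sample (V0) and a follow-up/onset sample (V1) profiled at
single-cell resolution (transcriptome + surface protein, paired TCR/BCR
sequencing, and single-cell chromatin accessibility). The package covers
the inference layers only; clustering, annotation and preprocessing are
inputs.

## Cluster-abundance association (mixed-effects logistic regression)

For each cell cluster j, the indicator that a cell belongs to j (one-vs-all
among cells of the same lineage) is modelled as

  logit P(Y_ij = 1) = theta_j + beta_age·age_k + beta_sex·sex_k
                      + phi_k [+ beta_case·case_k]

with a Gaussian random intercept phi_k ~ N(0, sigma^2) per sample k (and
optionally per batch and per dataset for integrated analyses, as
independent Gaussian intercepts). Because every covariate is sample-level,
the per-cell Bernoulli likelihood collapses exactly to per-sample binomial
counts, which is how the model is fitted. The marginal likelihood is
maximized under a Laplace approximation at the joint mode of the random
effects (for a single grouping factor an adaptive Gauss–Hermite option,
`nagq > 1`, is available; `nagq = 1` reproduces Laplace). Case association
is tested by a likelihood-ratio test of the full vs null model on 1 df,
and effect size is reported as OR = exp(beta_case) with a Wald 95% CI from
the inverted numerical Hessian of the marginal log-likelihood.

Numerical choices: outer optimization by BFGS on (beta, log sigma) with
finite-difference gradients, inner per-group Newton with step damping,
gradient tolerance 1e-6; a non-converged fit is retried once from a
perturbed start and otherwise flagged (`converged=False`), never dropped.
A cluster whose one-vs-all outcome is constant (the only cluster of its
lineage) is unidentifiable and is flagged rather than fitted.

Known limitation (measured, not fixable within the procedure): with ~40
samples the chi-square(1) reference for the LRT is mildly anticonservative
— the package measures a type-I error of ≈ 0.07 at nominal 0.05 on null
synthetic cohorts, and R's lme4 produces the same p-values (agreement to
~4e-6 on identical collapsed data). This is the well-known small-m
behaviour of GLMM likelihood-ratio tests, inherited faithfully from the
reference procedure.

## Repertoire diversity and somatic hypermutation

Clonal diversity uses the Hill-number family D_q = (sum_i p_i^q)^(1/(1-q))
over clone proportions p_i (cells per clone_id), with the Shannon limit
exp(-sum p_i log p_i) at q = 1 so the profile is continuous; q = 0 is
richness and large q is dominated by the largest clones. The default grid
is q = 0 to 4 in steps of 0.25. Diversity is computed on cells pooled per
(group, visit) by default; per-sample computation with averaging is
available behind the `mode` switch because the aggregation level is a
genuine free choice. Top expanded clones are the n largest clones per
grouping with lexicographic tie-breaking; public-TCR matching is exact on
the (CDR3 amino-acid sequence, V gene) pair after stripping allele
suffixes ("*01"), never fuzzy. Somatic-hypermutation distributions are
compared by the two-sample Kolmogorov–Smirnov test (asymptotic p), with
cumulative curves returned on a shared grid.

## CDR3 risk scoring and inference

A TCR beta-chain CDR3 of length 12–17 scores the sum of published
position-specific amino-acid effect sizes beta(length, position, residue);
any sequence outside that length range scores exactly 0, and uncovered
(length, position, residue) triples score 0. The coefficient table is a
plain TSV input.

**Zero-inflated Gaussian model.** Scores show a large spike at exactly 0.
Because a continuous Gaussian assigns probability zero to the point {0},
every exact zero is attributed to the structural component, and the
likelihood factorizes exactly: a logistic regression of the zero indicator
on CDR3 length, plus a Gaussian model of the non-zero scores with one cell
mean per group × visit and common sigma (ML estimate). This makes the fit
exact rather than EM-approximate, and the reported log-likelihood is the
sum of the two parts (an identity the tests verify). Directional
hypotheses ("Converter V1 > Converter V0" and the like) are one-sided z
contrasts on the conditional means. Optional per-sample random intercepts
in the conditional model (REML via statsmodels MixedLM) are off by
default; the iid-cell standard errors ignore clone-level correlation, so
contrast p-values on heavily clonal repertoires are anti-conservative —
the Bayesian layer and the sample-level aggregation are the robust
alternatives.

**Bayesian hierarchical comparison.** score ~ Normal(b[group:visit] +
a[length], sigma^2) with Normal(0,1) priors on the fixed effects b, a
CDR3-length random intercept a_l ~ N(0, tau^2), and half-Cauchy(0,1)
priors on tau and sigma (half-Cauchy because scales are nonnegative).
Cell-level analysis keeps lengths 12–17 (zeros retained by default, since
only the length filter is prescribed; a `keep_zeros=False` mode drops
them); sample-level analysis first averages scores per (sample, visit,
length). Sampling is 4 adaptive Metropolis-within-Gibbs chains × 2000
iterations (first half warmup): conjugate Gibbs updates for b and the
non-centered length effects, random-walk Metropolis on log tau and log
sigma with acceptance-rate adaptation during warmup, plus an interweaved
centered-parametrization update of tau (ASIS) so the chain mixes whether
the posterior for tau sits at zero or away from it. Convergence is
split-Rhat < 1.05 over all parameters; non-converged runs are flagged,
never hidden. Contrast results are fractions of post-warmup draws with a
positive difference; prob(A>B) + prob(B>A) = 1 by construction.

A single symmetric-null replicate's posterior probability is itself
approximately uniform (it tracks the realized group difference), so
calibration checks average prob_greater over seed-split replicates, where
the expectation is exactly 1/2.

## Differential expression and GSEA

DE is a per-gene two-sided Wilcoxon rank-sum test (midrank ties,
continuity correction) between two disjoint cell sets, with
log2FC = log2(mean(expm1 x_A)+1) − log2(mean(expm1 x_B)+1) — the dominant
single-cell convention, chosen because the source does not print the
formula. Significance requires |log2FC| > 1 (strict) and Bonferroni p
< 0.05. Pre-ranked GSEA uses the weighted Kolmogorov–Smirnov running sum
(weight |stat|) over genes ranked by average log2FC; gene-set members
absent from the ranking are dropped with a logged count and members
detected in fewer than 5% of cells are removed. The null is built from
random same-size gene sets drawn from the ranked universe (simpler than
the multilevel splitting of the original tool, same estimand);
NES = ES / mean(|null ES| of matching sign) and the permutation p carries
a +1 pseudocount against same-sign null ES, so p ≥ 1/(n_perm+1) and null
p-values are uniform regardless of the sign of the observed extremum.

## Converter-related chromatin peaks

The staged procedure: (1) pair peaks with genes whose ±500 kb window
around the TSS (strand-aware anchor; "centered on each gene" is ambiguous
and the anchor is configurable) contains the peak midpoint, half-open on
the right; (2) per gene, sum fragment coverage over its paired peaks and
keep genes in the top 25% (nearest-rank threshold, ties kept; a per-peak
variant sits behind a config switch since the prose supports either
reading); (3) within one lineage and visit, binarize accessibility and
skip peaks accessible in fewer than 5% of cells, or with a constant
outcome; (4) fit null/full binomial-logit models with age and sex fixed
effects and a per-sample random intercept (same GLMM core as the
cluster-association stage; a plain-GLM path is available), LRT on 1 df;
(5) flag Converter-related peaks by nominal p < 0.05 AND beta_case > 0.
Stage-by-stage record counts are logged and returned. Conservation of
flagged vs background peaks is compared by a one-sided rank-sum test on
per-peak overlap-weighted mean conservation scores (the track is an input;
intervals without coverage return NaN, never 0, and >10% missingness is an
error).

## Label transfer

Cross-modality label transfer takes any shared embedding as input and
assigns each query cell the majority label among its k = 30 Euclidean
nearest reference cells; vote ties break by smaller mean distance to the
tied classes, then lexicographic label, making the assignment
deterministic and order-invariant. The match rate is the row-normalized
contingency of predicted vs original labels with empty rows absent rather
than zero-filled. A shared-feature PCA utility builds embeddings for
synthetic tests; the original mosaic-integration embedding is out of
scope.

## Baseline prediction and survival

Feature importance is mean decrease in Gini impurity from a 500-tree
random forest (sqrt(p) features per split, bootstrap resamples; backed by
scikit-learn). AUROC uses the rank estimator with midrank ties and a
2000-replicate stratified bootstrap for the 95% CI (the CI method is
unstated in the source; the bootstrap is assumption-light and seeded). The
decision tree is rpart-style: greedy binary splits on midpoint thresholds
maximizing the prior-weighted Gini decrease with node class masses
m_c = prior_c · n_c(node)/n_c(root), equal priors (0.5, 0.5) by default,
maximum depth 4, minimum bucket 1, complexity parameter 0; leaves report
raw class fractions. Subjects are stratified per feature into bottom 20% /
middle 60% / top 20% using thresholds at the k-th smallest and k-th
largest values with k = floor(0.2 n) (this nearest-rank reading reproduces
the worked 1..10 example; ties at a threshold go to the outer bin). Cox
proportional hazards (Efron ties, via lifelines) reports HR with Wald 95%
CI per term, binned terms dummy-coded against the bottom bin; monotone
likelihoods are flagged non-converged. Kaplan–Meier curves use the
product-limit estimator, medians are the first time survival ≤ 0.5, and
groups are compared by the log-rank chi-square with hypergeometric
variance.

## Synthetic cohorts: what they emulate and what they do not

The generators are pure functions of their specs (seed included) and plant
effects on the scales the estimators measure, making every stage checkable
by parameter recovery:

- **Cohort**: two groups × two visits, one sample each; cluster counts are
  multinomial with logits shifted by the planted per-cluster log OR for
  Converters plus iid per-(sample, cluster) Gaussian intercepts
  (SD 0.2 — a moderate between-sample variability on the logit scale).
  Defaults are 20+20 subjects and 2000 cells per sample, the scale of the
  CITE-seq-like layers; the mass-cytometry-like 47+49 scale is a spec
  change away. The default catalogue of 12 clusters across T/B/NK/myeloid
  lineages puts the planted Tph cluster at 5% of cells.
- **Repertoire**: rank power-law clone sizes (exponent 1.2, 400 clones per
  sample — a CD4-dominated compartment is mostly singletons with an
  expanded tail), CDR3 lengths 8–20 peaked at 14, uniform residues;
  Converter residues are drawn from an exponentially tilted law with the
  tilt calibrated by root-finding so the expected risk score exceeds the
  Nonconverter expectation by exactly the requested shift. B cells carry
  isotypes and Beta-distributed mutation frequencies per (group, visit)
  whose default means mirror the observed SHM contrast (3.81% / 3.51% in
  Converters at V0/V1, slightly lower in Nonconverters).
- **Accessibility**: per-cell Bernoulli with logit(baseline 0.15) +
  planted effect for Converter cells at effect peaks + an independent
  per-(sample, peak) Gaussian intercept — independent per peak because
  that is the law the per-peak mixed model assumes, and it makes null
  peaks valid independent replicates; negative-binomial per-peak coverage;
  gene anchors every 250 kb so every peak falls in a window.
- **Survival**: Converters draw exponential event times with log hazard
  linear in standardized baseline features (baseline median 400 days);
  Nonconverters are censored at the 1095-day (36-month) horizon.

Not emulated: doublets and ambient contamination, batch effects on
expression, shared clones across visits, V(D)J generation biases,
covariate-dependent cluster composition (age and sex are pure noise), and
informative censoring. Passing recovery tests therefore demonstrates the
estimators are correct under their own assumptions, not that real-data
violations of those assumptions are handled.

## Problem sizes used in the shipped checks

Acceptance-level checks run at 20+20 subjects × 2000 cells/sample for the
cluster-association recovery, 500 replicate cohorts for null calibration,
n = 5000 for zero-inflated recovery with 50 replicate repertoires for
power, n = 2000 cells for the Bayesian comparisons, 200 random gene sets
for GSEA null uniformity, 500 independent null peaks (40 samples × 800
cells) for the directional-selection rate, and n = 200 subjects for Cox
recovery — sizes at which the Monte-Carlo error of each check is small
relative to its acceptance band.
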