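# Methods

## Model

`gainet` treats the expression of a gene as modulated by two upstream
regulatory layers. For gene *g* in sample *s*, with miRNA partners
*i = 1..n₁* (interaction scores IS_i, expressions e_i) and promoter CpG
partners *j = 1..n₂* (methylation fractions β_j):

- δ1(g,s) = (1/n₁) Σ_i [IS_i · exp(α·log2(e_i + pc))]⁻¹
- δ2(g,s) = (1/n₂) Σ_j exp(b·log2(β_j))⁻¹
- δ(g,s)  = (w1·δ1 + w2·δ2)/(w1 + w2)
- trans(g,s) = δ(g,s) · expr(g,s)

The factors are exponential-decay summaries of repression pressure: a highly
expressed partner miRNA with a strong interaction score drives δ1 far below
1; heavy promoter methylation (β → 1) drives δ2 toward 1 from above, while
low methylation (β → 0) lets δ2 grow. Each factor is an *average* over the
gene's partners, evaluated per gene and per sample — regulator state varies
by patient, so δ is a gene×sample matrix, not a per-gene constant. Both
factors are computed in log space (log-sum-exp over partner terms), so large
normalised counts cannot overflow the exponential.

Assumptions worth stating: regulation is multiplicative and memoryless
(partners contribute independently through the average); the two layers
combine linearly in δ; and the regulatory graphs are *inputs* — the package
never infers miRNA targets or CpG–gene assignments from sequence.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α (`alpha`) | 1.5 | decay sharpness of δ1 in partner miRNA expression; higher = narrower response |
| b (`beta_exp`) | 1.5 | same role for δ2 in log2 β |
| w1 : w2 | 1 : 1 | weight of δ1 vs δ2 in δ; the ratios 1:3, 2:3, 3:1, 3:2 are supported for ablation |
| `expr_pseudocount` | 1.0 | added inside log2 so zero counts stay finite |
| `is_floor` | 0.01 | lower bound of the normalised interaction score, bounding 1/IS |
| `beta_floor` | 1e-3 | β clamp; δ2 diverges as β → 0 (term = β^(−b/ln 2)) |
| `max_bad_fraction` | 0.20 | a feature/sample is dropped iff its zero-or-missing fraction *strictly* exceeds this |
| `tss_window_bp` | 1500 | CpG→gene edges kept for 0 ≤ distance ≤ window, inclusive |
| `missing_partner_policy` | fallback | gene with only one factor uses it alone; `neutral_one` substitutes 1 instead |

Interaction scores: raw TargetScan-style context scores are ≤ 0 with more
negative meaning stronger repression. They are normalised by |raw| followed
by min–max onto [`is_floor`, 1], which preserves the "stronger interaction →
larger IS → stronger downweighting" ordering while bounding the 1/IS term; a
degenerate table (all scores equal) maps to IS = 1. Other normalisations
(e.g. sum-to-one) would change only the scale of δ1, not its ordering.

## Preprocessing

Per omic, features are filtered before samples, then samples present in all
three omics are kept (ordered by the first matrix); this order is fixed
because the result depends on it. Counts are normalised with median-of-ratios
size factors (per-feature geometric-mean reference over samples, restricted
to features positive everywhere; per-sample factor = median ratio) — the
implementation is cross-checked in the tests against pyDESeq2's
normalisation. β matrices are median-imputed per feature and clamped to
[`beta_floor`, 1]. BMIQ-style probe-type normalisation is out of scope: it
needs array-design metadata absent from a generic β matrix, and the
transform only needs β ∈ (0, 1].

One estimator subtlety: median-of-ratios size factors use a self-referential
geometric-mean reference, so scaling one sample's column by *c* rescales the
reference by c^(1/n) and the whole normalised matrix by that common factor;
relative structure is exactly preserved, which is what the tests assert.

## Classification

Features are standardised on training statistics only; augmentation runs on
the training partition only, and the tests assert the test rows leave the
pipeline bit-identical. The four families are one-vs-rest logistic
regression, kNN (k = 4), random forest, and a feed-forward net with three
ReLU hidden layers (default 256/128/64, configurable), softmax output, Adam
and cross-entropy loss. The "overall AUROC" is the unweighted macro average
of one-vs-rest per-class AUROCs, skipping classes the test partition cannot
score; per-class precision/recall/F1 use the zero convention for empty
denominators. Cross-validation is stratified, default 5 folds;
`pooled_cv_report` pools the held-out predictions of all folds into one
confusion matrix, a lower-variance summary than averaging per-fold metrics
when minority classes put only a few samples in each fold.

Minority balancing is ADASYN-style and implemented natively: every class is
topped up to the majority count; each minority sample receives a share of
the budget proportional to the fraction of its k nearest neighbours (k = 5,
over the whole training set) belonging to other classes, and each synthetic
point is a convex combination x_i + u·(x_z − x_i), u ~ U(0,1), of the sample
and one of its k nearest same-class neighbours. Classes too small for
neighbour search fall back to duplication with a warning. All draws flow
from a single `numpy` Generator seeded per call.

## Explanation

The default importance backend computes exact path-dependent Shapley values
for tree ensembles (the polynomial tree-traversal algorithm over the game
v(S) = E[f(x)|x_S] under the tree's training cover), implemented in
`gainet._treeshap` and verified against a brute-force subset-enumeration
Shapley oracle on small trees; local accuracy (Σφ + baseline = prediction)
is asserted for forests. Global importance is the mean |φ| over samples and
classes; per-class columns carry per-class means. A model-agnostic seeded
permutation backend is the fallback for non-tree models.

The annotation cascade keeps a gene iff (SIFT ∈ [0, 0.05] OR PolyPhen ∈
[0.85, 1.0], both inclusive — AND available via a flag) and its
haploinsufficiency score is strictly positive; genes with all scores missing
are dropped and counted separately. Per-subtype gene lists are the per-class
top-k of the ranking (k = `top_k`/4 in the pipeline), and their
unique/shared structure is exact set algebra.

## Survival

High/low groups split at the median of expression with ties going low (the
quantile is configurable); the Kaplan–Meier estimator and the two-group
log-rank χ²(1) test are provided by `lifelines` behind the module surface,
with hand-computed product-limit and hypergeometric-table oracles as
independent checks in the tests. Two identical groups give statistic 0 and
p = 1; if neither group has any event the statistic is reported as undefined
(NaN), never 0. Screening flags p < 0.05 strictly, uncorrected by default to
match per-gene reporting practice; Benjamini–Hochberg is available via a
flag. Only overall survival is modelled — no Cox regression or competing
risks.

## Synthetic cohorts

The generator emulates a small imbalanced four-class cohort: 100 samples
(45/25/15/15), 80 genes, 120 miRNAs, 150 CpGs. Counts are negative-binomial
(mean ≈ 200 for mRNA, ≈ 100 for miRNA, dispersion 0.3 — overdispersion
typical of RNA-seq), β values Beta-distributed (concentration 30), and
promoter distances uniform on [0, 1500] bp. A fifth of the genes are signal
genes owning *disjoint* regulator sets; per class and signal gene one
coherent direction is drawn, and all of that gene's partner miRNAs shift by
±1.0 log2 units and partner CpGs by ±1.2 logit units in that direction —
emulating a subtype-specific regulatory programme. Coherence is essential:
δ averages over a gene's partners, so aligned shifts accumulate while
independent per-regulator signs would largely cancel. mRNA means are the
baseline times a suppression factor decreasing in the sampled partner miRNA
levels and mean promoter β, so class structure reaches the mRNA matrix only
through the regulatory graph. One signal gene is prognostic: samples above
its median expression draw exponential survival times at 3× the baseline
hazard (0.05 per time unit), administratively censored at t = 30.

What the generator does *not* emulate: real cohort dimensionalities
(tens of thousands of features), batch effects, probe-type artefacts,
missing-at-random structure beyond simple NA planting, correlated regulator
programmes across genes, or empirical subtype proportions. Passing tests
therefore demonstrate correctness and the qualitative signal-concentration
property at desk scale, not real-data performance levels.

Problem sizes throughout the suite (100-sample cohorts, ≤ 10-gene oracle
instances, 500 null replicates for the type-I check) were chosen as the
smallest at which the tested properties are statistically meaningful.

## Numerical choices

- δ1/δ2 partner sums use `scipy.special.logsumexp`; identical inputs give
  bit-identical outputs.
- Oracle agreement between the vectorised transform and the per-edge
  reference evaluator is asserted at 1e-9 *absolute* on δ; the transformed
  matrix (δ × counts, reaching ~1e6 on random instances, where 1e-9 absolute
  is below one float64 ulp) is asserted at 1e-9 *relative*.
- Ties: dichotomisation sends values equal to the median to "low";
  importance sorting is stable, so equal scores keep input order.
- Degenerate inputs raise typed errors rather than warning and continuing:
  all-features-removed, empty sample intersection, no all-positive feature
  for size factors, all-missing β feature, constant expression at
  dichotomisation, zero usable graph edges.
- The pipeline derives stage seeds as `seed + stage_index` so stages can be
  re-run in isolation; manifests hash only deterministic content, making
  double-run comparison exact.

## Open design points resolved here

- Per-gene reading of the miRNA factor: n is the number of miRNAs
  interacting with *that* gene, summed per sample — the only reading that
  yields a gene- and sample-specific factor usable in the final product.
- The interaction-score normalisation is a documented default (|raw| then
  min–max), swappable by preprocessing the table before input.
- mRNA expression enters the final product un-logged by default; a
  log2(x+1) pre-transform is available as a config flag.
- Genes lacking partners in one graph default to the available factor alone
  ("fallback") rather than being dropped — silently shrinking the feature
  space would be worse than an asymmetric factor.
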