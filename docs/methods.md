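# Methods

`ddascan` scores *groups* of SNPs — genes or pathways — for association with
a binary phenotype, including the aggregated effect of all pairwise
interactions among the group's SNPs.  This note describes the model, the
statistical procedure, the synthetic data the tests run on, and the
numerical and design choices made where more than one defensible option
existed.

## The discriminant model

Genotypes are minor-allele counts g ∈ {0, 1, 2}.  Each SNP is encoded under
the *genotypic* model: category 0 (major-allele homozygote) is the
reference and categories 1 and 2 each get a binary indicator, so a SNP
contributes two free field parameters and a pair of SNPs a 2×2 block of
couplings — four free parameters per pair.  No additive (dosage) constraint
is imposed, so dominance and heterozygote-specific effects are
representable.

Per phenotype class y ∈ {0, 1} the model is a pairwise discrete
exponential-family (Potts-like) distribution with fields h and couplings J,
fitted by naive mean-field inversion:

1. Category frequencies with pseudocount λ:
   f_i(a) = (n_i(a) + λ) / (n + 3λ), and joint frequencies with λ/3 per
   cell: f_ij(a,b) = (n_ij(a,b) + λ/3) / (n + 3λ).  The λ/3 scheme makes
   the marginal identity Σ_b f_ij(a,b) = f_i(a) hold *exactly*, keeps all
   logs finite, and keeps the within-SNP covariance blocks nonsingular.
2. Indicator covariance over non-reference categories:
   C_(i,a),(j,b) = f_ij(a,b) − f_i(a) f_j(b) for i ≠ j and
   C_(i,a),(i,b) = f_i(a) δ_ab − f_i(a) f_i(b) within a SNP.
3. Regularization: C(ε) = D + ε (C − D), where D is the within-SNP block
   diagonal of C and ε ∈ [0, 1].  ε = 0 removes all cross-SNP structure;
   ε = 1 keeps the full covariance.
4. Couplings are the negated cross-SNP blocks of K = C(ε)⁻¹; within-SNP
   entries of K are discarded.  At ε = 0, C is block-diagonal, its inverse
   has no cross-SNP entries, and J ≡ 0 exactly.
5. Fields: h_i(a) = ln(f_i(a)/f_i(0)) − Σ_{j≠i,b} J_(i,a),(j,b) f_j(b),
   the mean-field closure that reproduces the observed single-site
   frequencies.

An individual's score is the difference of class log-unnormalized
likelihoods,

    s(x) = Σ [h¹−h⁰]·x + ½ Σ_{i≠j} [J¹−J⁰]·x x,

with the partition-function constants dropped: the AUC is a rank statistic
and is invariant to any constant shared shift, which the test suite checks
explicitly.  At ε = 0 the score reduces exactly to the sum of per-SNP
log-frequency ratios — the independent-loci (IL) special case — so one
parameter continuously interpolates between "no interactions" and "full
mean-field interactions" (CL).

The exact mean-field equations above are pinned as this package's
construction; they satisfy every property the scoring procedure needs
(2 df per SNP, 4 df per pair, exact IL reduction at ε = 0, continuous
shrinkage of |J| to 0 as ε → 0).

## Group scoring and ε optimization

A group's statistic is the mean held-out AUC under seeded stratified
5-fold cross-validation: 80% of individuals fit the two class models, 20%
are scored.  ε is selected by maximizing this cross-validated AUC over the
grid {0, 0.1, …, 1.0}; every grid value is evaluated on the *same* fold
partition, so the reported CL AUC is never below the IL (ε = 0) AUC by
construction.  Ties resolve to the smallest ε.  Grid resolution 0.1 is a
default, configurable in `ScanConfig`.

Folds are stratified by phenotype (each fold's class ratio matches the
sample's to within one individual), which guarantees both classes in every
fold even at skewed case:control ratios such as the 61:1131 split of the
dichotomized mouse glucose design.  The fold partition depends only on
(labels, K, seed).  Mean-over-folds AUC is used rather than
pooled-prediction AUC; fold-wise scores are not calibrated to a common
scale, so pooling would mix incomparable score distributions.

Missing genotypes are imputed per fold with the training-set modal
genotype (ties toward the smaller genotype); test samples never influence
the modes.

## Permutation calibration

The ε-optimized cross-validated AUC is optimistically biased as a test
statistic — the maximum of K noisy curves sits above 0.5 under the null.
The null distribution is therefore built by phenotype-label permutation
with ε re-optimized *for every replicate*, reproducing the selection
effect.  The permutation p-value uses the add-one estimator
p = (1 + #{null ≥ observed}) / (R + 1), which can never be zero and gives
exactly valid finite-sample inference; at large R the difference from the
raw fraction is negligible.  R defaults to 1000 and is configurable; the
test suite uses R = 199 (null-uniformity) and R = 100 (calibration) to
keep simulations tractable at desk scale.

Because permutations are expensive, the full pipeline permutes only a
calibration subset — groups at or below a SNP-count quantile (default
0.25, optionally capped), since small groups are cheapest and span the
null AUC range — and fits a quadratic orthogonal-polynomial regression of
log₁₀(p) on AUC (thin-QR orthonormal basis; numerically stable
prediction).  The log scale is used because permutation p-values span
orders of magnitude; the fit is flagged if non-monotone inside the fitted
AUC range, and predictions outside that range are flagged as extrapolated.
IL p-values are calibrated from the ε = 0 AUCs of the same permutation
replicates, which cost nothing extra and have the correct (un-optimized)
null distribution.

Family-wise control uses the Bonferroni threshold α/m; FDR control uses
Benjamini–Hochberg step-up q-values.

## Group construction

SNPs are assigned to a gene when their 0-based position falls in
[start − w, end + w) with w = 50 kb (lower bound clamped at 0); a SNP may
belong to several genes.  Pathway groups are unions of member genes' SNP
sets with a 20-SNP minimum by default; gene mode defaults to a 1-SNP
minimum.  Groups with identical SNP content collapse to one record (the
lexicographically smallest name is primary, the rest become aliases), so
each unique SNP set is tested once.

LD pruning is a greedy pass over the whole group in (chrom, pos) order:
monomorphic SNPs are dropped first, then a SNP is kept only if its squared
Pearson correlation of allele counts with every already-retained SNP is at
most r²_max (default 0.9, missing pairs excluded).  Checking against *all*
retained SNPs rather than a sliding window is affordable at group scale
and yields a strictly stronger guarantee (no retained pair anywhere above
the cap); pruning is idempotent and never empties a group.

## Numerical choices

- Pseudocount λ = 0.5 per genotype category (λ/3 per joint cell).
- C(ε) is symmetric positive definite in exact arithmetic ((1−ε)D + εC
  with D ≻ 0 thanks to the pseudocounts), so it is inverted directly; if
  the 1-norm condition estimate ‖C‖₁‖C⁻¹‖₁ exceeds 10¹² (cap
  configurable), a ridge δ·tr(C)/(2m) with δ = 10⁻⁶ is added and the
  inversion retried, with a logged warning.  The 1-norm estimate is exact
  to compute and within a factor of the matrix dimension of the 2-norm
  condition number; with pseudocounted frequencies even perfectly
  duplicated SNP columns stay far below the cap, so the ridge is a safety
  net for extreme LD, not a routine code path.
- AUC is computed from midranks (ties count half), identical to the
  Mann–Whitney definition and cross-checked against brute-force pair
  enumeration and scikit-learn in tests.
- The IL single-SNP test is the likelihood-ratio (G-) statistic on the
  2×3 phenotype-by-genotype table with expected counts from the margins;
  genotype categories empty in the pooled sample are dropped with the df
  reduced and flagged.  Zero observed cells contribute zero.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not any particular cohort:

- **Genotypes**: Gaussian-copula haplotypes — a latent normal with
  block-constant correlation ρ thresholded at Φ⁻¹(1 − MAF), genotype =
  sum of two independent haplotypes.  Marginals are exactly in
  Hardy–Weinberg equilibrium at the target MAF; block-constant LD is
  enough to exercise pruning and near-collinear covariance handling.
  This deliberately omits realistic LD decay, allele-frequency spectra,
  demography and genotyping error, so passing tests show correctness of
  the inference machinery, not calibration on real cohort structure.
- **Phenotypes**: logistic penetrance with additive main effects, centered
  product-term interactions, and/or explicit 3×3 log-odds increments per
  pair; case-control ascertainment draws genotype rows until exact quotas
  are met (ascertainment shifts the intercept, not the effect sizes, which
  a regression-recovery test verifies).
- **Pure epistasis (carrier-XOR)**: a log-odds increment γ fires when
  exactly one SNP of a pair carries ≥ 1 minor allele.  At MAF
  = 1 − √½ ≈ 0.2929 the carrier probability is exactly ½, so the
  increment probability is ½ regardless of either SNP's own genotype —
  marginal effects are *provably* zero while the pair stays informative.
  This is the cleanest possible IL-vs-CL contrast: per-SNP tests see
  nothing, collective inference sees the pairs.  The canonical scenario
  uses n = 2000 balanced samples, one 40-SNP causal group containing five
  such pairs at γ = 1, and ten null groups of the same size.
- **Quantitative traits**: linear predictor plus Gaussian noise, for the
  dichotomize-at-threshold design (strictly-greater comparison, as in a
  glucose > 14.0 mmol/L case definition).

Problem sizes in the test suite (n = 300–2000, 10–100 groups, R = 100–199)
were chosen so the whole suite runs on a single CPU in minutes while every
statistical property retains comfortable power; they are smaller than a
genome-wide analysis, and the calibration r² threshold (0.8) is
accordingly looser than the near-perfect correlation seen at cohort scale.

## Known limitations

- The mean-field inversion is an approximation; couplings are biased for
  strongly dependent SNPs, which is acceptable here because J enters only
  through a cross-validated discriminant score, never as an estimand.
- The AUC→p regression interpolates; groups with AUC outside the
  calibration range are flagged as extrapolated and their p-values should
  be confirmed by direct permutation.
- Bonferroni across pathways is conservative when pathways overlap; no
  hierarchy-aware correction is attempted.
- The fixture writer requires designed gene→SNP assignments to be disjoint
  across genes (pathway-level overlap is expressed in the GMT instead).
- Ascertainment in the simulator regenerates whole genotype rows; it does
  not model dosage uncertainty or genotyping batch effects.
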