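# Methods

## The estimand: omics-explainability

Each omics layer (rumen microbial species, KO functions, rumen
metabolites, serum metabolites) is summarized as an n × n sample
relationship matrix and entered as the covariance of a single random
effect in a linear mixed model for the trait:

    y = Xβ + g + e,   g ~ N(0, M σ²_omics),   e ~ N(0, I σ²_e).

The fixed effects X are an intercept, treatment-coded parity (reference =
lowest observed level) and mean-centered lactation days. Four models are
fit independently, one per layer — there is no joint multi-kernel model,
mirroring the four-equation structure this analysis style uses. The
reported explainability is m² = σ²_omics/(σ²_omics + σ²_e), the
model-implied variance fraction. Using the model-implied denominator
(rather than the raw sample variance of y) keeps m² in [0, 1] by
construction; a `sample variance` alternative would differ only when the
model fits poorly.

## Relationship matrices

Features are z-scored across samples (sample variance, denominator n−1;
zero-variance features dropped and reported) and the kernel is M = Z Zᵀ/p.
Consequences used as exact test invariants: trace(M) = n−1, row sums 0,
M PSD, and invariance of M to positive rescaling of any raw feature.
Explainability itself is invariant to a global rescaling of M (absorbed
into σ²_omics), so the choice of the 1/p normalization affects variance
units only. Metabolite concentrations are z-scored on their raw scale by
default; the log2 transform is reserved for the multivariate metabolome
stage, where the source protocol applies it (a `log2_first` flag enables
log-first standardization).

## REML implementation

With a single kernel the restricted likelihood profiles analytically down
to one parameter. M is eigendecomposed once (eigenvalues clipped at 0
against round-off); y and X are rotated into the eigenbasis; for a given
λ = σ²_omics/σ²_e the GLS β and σ̂²_e have closed forms and the restricted
log-likelihood (including the +½log|XᵀX| convention, making it invariant
to reparametrizations of X) costs O(n·q). Optimization: a 128-point
log-spaced global scan over λ ∈ [1e−6, 1e6] followed by bounded scalar
minimization (xatol 1e−10 on log λ) in the best bracket; the scan keeps
the search global since the profiled likelihood can in principle be
multimodal. The boundary λ = 0 (ordinary least squares, σ²_omics = 0) is
always evaluated and wins ties, reported with a boundary flag. A kernel
with numerically equal eigenvalues (M ∝ I) makes only σ²_omics + σ²_e
identifiable; this is flagged rather than erroring. An approximate
standard error for m² comes from finite-difference curvature of the
profiled likelihood in h = λ/(1+λ) (NaN at boundaries). Correctness is
established against an independent dense-matrix REML evaluation (explicit
inverses and slogdets, no rotation): the rotated optimum must dominate a
1,000-point dense grid and agree with the dense value to 1e−8.

## Synthetic studies

The generator is the package's test bed: it emulates the *structure* of a
24-animal, two-group (12 HH / 12 LL) processed-table study, not rumen
biology. Choices and defaults:

- **Abundances.** Per-feature log-normal baselines (log-SD 2.0 across
  features, giving the heavy-tailed rank-abundance profile typical of
  species tables) with per-sample log-noise SD 0.5 (the realistic low end
  of intra-group variation in processed tables). Microbial layers are
  closed to sum 1 per sample; metabolome layers stay unclosed positive
  concentrations. Default feature counts: 500 species, 2,000 KOs, 1,714
  rumen and 1,356 serum metabolites (catalogue-scale species/KO counts are
  scaled down to keep matrices small; metabolite counts match typical
  panel sizes).
- **Planted differential features.** The group-specific mean of a planted
  feature is multiplied by its fold-change (default: first 20 features of
  each layer, 3-fold up in HH) *before* closure. Closure therefore
  produces genuine compensatory dilution of all other features — a real
  property of compositional data that the differential screens must
  contend with, not an artifact.
- **Phenotypes.** y = μ + parity effects + lactation slope + g + e with
  g = Z a/√p, a ~ N(0, σ²_omics) computed from the standardized driving
  layer (default: microbial composition, m² = 0.34; per-layer defaults
  0.34/0.47/0.39/0.50 follow the proportions this analysis style reports
  at field scale and serve as realistic settings, not as expected
  estimates). Cov(g) = M σ²_omics exactly, so the estimator's assumed law
  holds by construction. A `combined` mode sums per-layer contributions
  (their m² must total ≤ 1); it is an extension beyond the four separate
  models and is labeled as such in the ground-truth record. Trait scales:
  milk yield mean 9 kg/day, total random variance 4; milk fat yield mean
  0.65 kg/day, variance 0.04. Fixed-effect defaults are small relative to
  the trait SD so explainability recovery dominates.
- **Phenotype-associated metabolites.** After phenotype generation, 10
  features in each metabolome layer are rewritten as exp(z(y) + ε),
  ε ~ N(0, 0.3²) — noisy monotone functions of milk yield — giving the
  correlation-network stage a known answer. A side effect worth knowing:
  metabolome layers then genuinely explain ~100% of the trait at n = 24,
  and the KO layer inherits partial group structure from its own planted
  features, so non-driving layers are not null layers.
- Group labels are assigned a priori and influence the phenotype only
  through the planted features' contribution to g; there is no separate
  group term in y (the mixed model has none).

What passing tests on this generator do **not** show: robustness to
real-data features it omits — phylogenetic/pathway correlation among
features, measurement batch effects, zero inflation, missing values, or
any causal structure between layers beyond the planted constructs.

## Differential screens

- `permutation_test` (single feature) uses the Welch t statistic with
  p = (1 + #{|t_perm| ≥ |t_obs|})/(1 + B), switching to exact enumeration
  of all C(n, n₁) assignments (p = count/total) whenever that is ≤ B.
- `metastats_screen` shares one drawn permutation set across features and,
  by default, pools the permuted |t| statistics of all features into one
  null distribution (resolution 1/(B·m) instead of 1/B). Without pooling,
  every strongly differential feature ties at the floor 1/(B+1), and
  Benjamini–Hochberg at m = 500 features then needs ≥ 10 floor-tied
  features before *any* is called at q < 0.05 — a resolution pathology,
  observed in practice, that pooling removes. The t statistic is
  scale-free, which is what makes the pooled null exchangeable across
  features. Per-feature mode remains available (`pooled=False`).
- The LDA effect-size screen is a deliberate simplification of the
  published two-class procedure: per-million rescaling, two-sided rank-sum
  gate at α, effect size log10|mean difference| floored at 0, significant
  iff p < α and score > 2. It reproduces the conventional score scale and
  threshold behavior without the original tool's bootstrap internals, and
  is documented as such; agreement with that tool is expected at the
  threshold-decision level, not score-by-score.
- BH FDR is implemented from the step-up definition (and cross-checked
  against statsmodels in tests) so the q-value contract is explicit.

## Metabolome multivariate stage

OPLS-DA follows the orthogonal-projections scheme: per orthogonal
component, the y-orthogonal part of the X loading is removed from X; one
predictive component is then fit on the filtered matrix. Class coding is
+1/−1 (first group level in sorted order is +1). Input is log2-transformed
and mean-centered only (no unit-variance or Pareto scaling by default;
a flag can standardize). Q² uses seeded venetian-blind 7-fold
cross-validation; permutation validation refits on permuted labels,
p = (1 + #{Q²_perm ≥ Q²_obs})/(1 + B), minimum attainable 1/(B+1). With
unit-norm weights the VIP reduces to √p·|w_j|, satisfying mean(VIP²) = 1
exactly — kept as a test identity. The univariate gate feeding
"FDR q < 0.05" is a Welch t-test on the log2 data (rank-sum optional).
Selection requires VIP > 1 AND q < 0.05, both strict. Pathway enrichment
is the hypergeometric upper tail P(X ≥ k) on the annotation universe, with
BH across pathways.

## Ordination

Bray–Curtis is Σ|u−v|/Σ(u+v) (via scipy's pdist). PCoA Gower-centers
−½D², eigendecomposes, drops negative-eigenvalue axes with a flag (no
Lingoes/Cailliez correction) and fixes each axis sign by making its
largest-magnitude coordinate positive. PERMANOVA is the one-factor
pseudo-F on squared distances, F = (SS_b/(a−1))/(SS_w/(n−a)), with label
permutations (exact enumeration for two groups when feasible); the
identity F = (R²/(a−1))/((1−R²)/(n−a)) holds exactly and is tested, and
the pseudo-F is cross-checked against scikit-bio. Default 999
permutations.

## Correlation networks

Spearman with mid-ranks; p from the large-sample t approximation (the
choice matters only near the gate at n = 24 and is documented rather than
hidden). The significance gate is strict: |ρ| > 0.5 and p < 0.05, with no
multiple-testing correction by default — an optional BH mode exists but is
off to match the quoted convention. Block correlation is computed as
Pearson on rank-transformed columns for all pairs at once.

## Numerical conventions and degenerate inputs

Ties in permutation statistics are compared with a 1e−12 slack so exact
ties count as exceedances. Two constant equal groups give t = 0, p = 1;
fold changes with zero denominators are NaN, not errors. All-zero samples
are rejected by Bray–Curtis with the sample named. Zero-variance features
are dropped (standardization) or excluded (LDA screen) with reporting.
Every stochastic routine takes an explicit seed; the pipeline derives all
stage seeds from the run config seed, and identical config + seed yields
byte-identical output tables.

## Problem sizes in the shipped checks

Calibration simulations use n = 300 animals, p = 500 features, 50
replicates per true m² (recovery to ±0.05; null median ≤ 0.05); study-scale
behavior is characterized at n = 24, where single-study estimates are
bimodal near 0/100 and only ensemble summaries are meaningful. PERMANOVA
type-I error uses 500 null datasets of 12 samples at 199 permutations.
These sizes were chosen to make sampling error comfortably smaller than
the effects being checked while keeping the checks quick to run.

## Known limitations

- Single random effect per model: no joint decomposition across layers,
  so correlated layers each absorb shared signal (visible in the
  generator: non-driving layers show nonzero explainability through
  cross-layer structure).
- At n = 24 the REML estimate of m² has near-boundary bimodal sampling
  spread; single-study numbers should be read with the calibration
  simulations in mind.
- The LDA screen and the OPLS-DA scaling are documented simplifications
  of proprietary/unpublished tool internals; fidelity is at the level of
  thresholds and decisions.
- Compositional closure induces real spillover differences in non-planted
  features; the screens treat abundances as given and make no
  compositional (e.g., log-ratio) correction, matching the emulated
  workflow.
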