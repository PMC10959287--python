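# lactomics

How much of a milk-production trait can each omics layer explain?

`lactomics` is an analysis pipeline for two-group (high vs low yield)
multi-omics studies of ruminant milk production that start from processed
feature tables: species-level rumen microbial relative abundances, KEGG
ortholog (KO) functional abundances, and rumen/serum metabolite
concentrations, together with per-animal phenotypes (milk yield and milk
fat yield in kg/day, parity, lactation days). It is written for
quantitative microbiome / animal-science researchers who want the
"microbiability"-style variance-component analysis and the surrounding
comparative statistics as tested, scriptable Python rather than a chain of
one-off tools.

## The model

For each omics layer the pipeline fits, by restricted maximum likelihood
(REML), the linear mixed model

```
y = Xβ + g + e,      g ~ N(0, M σ²_omics),      e ~ N(0, I σ²_e)
```

where `y` is the trait, `X` holds the intercept, treatment-coded parity and
centered lactation days, and `M = Z Zᵀ / p` is the layer's sample
relationship matrix built from the column-standardized (z-scored,
denominator n−1) layer matrix `Z` with `p` features — the microbiome
analogue of a genomic relationship matrix. The reported
**omics-explainability** is

```
m² = σ²_omics / (σ²_omics + σ²_e)
```

the model-implied fraction of phenotypic variance attributable to the
layer. The fit eigendecomposes `M` once, rotates `y` and `X` into the
eigenbasis, and maximizes the profiled restricted likelihood over the
single variance ratio λ = σ²_omics/σ²_e by a global grid scan plus bounded
scalar refinement, so each evaluation is O(n·q); the boundary σ²_omics = 0
is always evaluated explicitly.

Around the variance components the package implements the standard
two-group comparison stack:

- **differential screens** — Welch t-tests with HH/LL fold changes, a
  Metastats-style permutation t-test with Benjamini–Hochberg FDR (pooled
  permutation null for p-value resolution 1/(B·m)), and a two-class LDA
  effect-size screen (per-million rescaling, rank-sum gate, log10 mean
  difference > 2);
- **metabolome multivariate** — OPLS-DA (log2 + mean-centering, one
  predictive plus configurable orthogonal components), VIP scores
  (mean VIP² = 1), 200-permutation model validation, VIP > 1 ∧ FDR q < 0.05
  metabolite selection, and hypergeometric pathway enrichment;
- **ordination** — Bray–Curtis dissimilarity, PCoA (Gower double-centering,
  negative eigenvalues flagged and dropped), one-factor PERMANOVA with
  permutation p (exact enumeration when feasible);
- **correlation networks** — all-pairs Spearman with the strict
  |ρ| > 0.5 ∧ p < 0.05 gate, phenotype-associated feature sets split by
  sign, and Venn-style shared-feature comparisons.

A synthetic-study generator (`lactomics.simulate`) produces all four layers
plus phenotypes under exactly this mixed-model law with known ground truth
(target m² per layer, planted differential features with configured fold
changes, planted phenotype-associated metabolites), so every stage is
testable end to end without access to a real study.

## Worked example

Generate a 24-animal study (12 HH / 12 LL) whose milk yield is driven by
the microbial-composition layer at true m² = 0.34, then estimate each
layer's explainability:

```
$ lactomics simulate --seed 5 --out study
wrote synthetic study (24 samples) to study
```

```python
from lactomics.io import read_feature_table, read_phenotype_table
from lactomics.explainability import explainability_table

layers = {l: read_feature_table(f"study/{l}.tsv", l) for l in
          ("microbial_composition", "microbial_function",
           "rumen_metabolome", "serum_metabolome")}
ph = read_phenotype_table("study/phenotypes.tsv")
print(explainability_table(layers, ph, ("milk_yield",)))
```

```
                layer      trait  explainability_pct  sigma2_omics  sigma2_resid  converged
microbial_composition milk_yield               45.08      1.952762      2.379194       True
   microbial_function milk_yield                0.00      0.000000      4.322014       True
     rumen_metabolome milk_yield              100.00      3.866171      0.000004       True
     serum_metabolome milk_yield              100.00      4.005042      0.000004       True
```

The driving layer estimates 45% against a ground truth of 34% — at n = 24
single-study estimates are extremely noisy (they often land on the 0/100
boundary; calibration simulations at n = 300 recover the truth to ±0.05).
The metabolome layers report ~100% because the generator plants metabolites
that are monotone functions of milk yield, so those layers genuinely carry
near-perfect information about the trait. The full pipeline
(`lactomics all config.yaml`) adds the differential, OPLS-DA, ordination
and network stages and writes TSV tables plus a JSON run manifest;
identical config and seed give byte-identical outputs.

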