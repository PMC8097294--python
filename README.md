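# dimorph

Quantitative genetics of sexual dimorphism in gene expression.

Sexual dimorphism in expression is usually read as evidence of sexually
antagonistic selection (SAS) — selection pushing male and female trait
values apart. But dimorphism also evolves as an *indirect* response to
sexually concordant selection (SCS) whenever the sexes differ in genetic
variance or in cross-trait covariance structure. `dimorph` implements the
multivariate machinery to quantify both routes and to interrogate which
parts of a sex-specific genetic covariance matrix drive them, together
with a complete analysis pipeline for inbred-line expression panels
(e.g. a DGRP-style design: ~40 lines × 2 sexes × 2 replicate chips,
log2-scale intensities). It is aimed at evolutionary quantitative
geneticists working with expression (or any multivariate) phenotypes
measured in both sexes.

## The model

Responses to one generation of selection follow the two-sex breeder's
equation

```
[Δz̄_M]   1 [ G_M   B  ] [β_M]
[Δz̄_F] = ─ [ Bᵀ   G_F ] [β_F]
          2
```

where `G_M`, `G_F` are the within-sex genetic covariance blocks and `B`
holds cross-sex covariances (male rows × female columns; its diagonal
over the geometric-mean variances gives the intersexual correlation
r_MF). The change in dimorphism is Δ = Δz̄_M − Δz̄_F over shared traits.
Two decompositions organize everything:

* **Antagonistic selection** (β_M = −β_F) sees only the sex-averaged
  block Ḡ = (G_M + G_F)/2 and the symmetric part B_S = (B + Bᵀ)/2:
  Δ_A = (Ḡ − B_S) β_M. For one trait, Δ_A = β ḡ (1 − d·r_MF) with
  d = √(mf)/ḡ, the ratio of geometric to arithmetic mean of the sex
  variances — d is 0.94 at a 2:1 variance ratio and does not fall to ½
  until the ratio is ~14:1.
* **Concordant selection** (β_M = β_F) sees only the asymmetries:
  Δ_C = ((G_M − G_F)/2 + B_A) β_M with B_A = (B − Bᵀ)/2; for one trait
  Δ_C = β (m − f)/2 = β ḡ √(1 − d²). SCS outpaces SAS of equal strength
  whenever d < 2 r_MF/(r_MF² + 1).

The package provides these closed forms (one-trait, two-trait indirect
and both-selected cases), the general engine with evolvability `e`,
respondability `R`, ‖Δ‖ and male/female response vector correlations,
conditional (stabilizing-selection-constrained) responses, and the
matrix-modification experiments that substitute Ḡ, B_S or 0 into the
matrix to isolate which asymmetries matter.

Around that core sit the panel pipeline stages: a REML likelihood-ratio
screen for genetic variance per gene (line + line×sex [+ line×probe]
random effects, retention at P < 0.01), least-squares line means,
dimorphism D = z̄_M − z̄_F with bias classes (MB: D > 1, FB: D < −1,
UB: |D| ≤ 1), per-gene genetic summaries (m, f, b, r_MF, ḡ, d) and
aggregate cross-gene correlation statistics, a line-level bootstrapped
multiple regression of log10(|D| + 0.01) on those summaries, bias-class
PCA trait construction, G-matrix estimation with AICc rank selection and
Wishart uncertainty propagation, and a synthetic-panel generator with
fully known architecture.

## Worked example

A built-in synthetic 12-trait reference matrix (4 unbiased traits shared
between sexes, 2 male-only, 2 female-only; diagonal-B correlations
averaging 0.82) makes the response machinery concrete:

```python
import dimorph as dm
from dimorph.response import summarize_over_gradients

g = dm.table2_reference_g()
print(g.r_mf)         # UB1 0.60, UB2 0.95, UB3 0.74, UB4 0.99
grads = [dm.SelectionGradient.antagonistic(g, ["UB1"]),
         dm.SelectionGradient.concordant(g, ["UB1"])]
print(summarize_over_gradients(g, grads))
print(dm.modification_ratio_table(g, grads, ["avg_G", "avg_G_sym_B"]))
```

prints (abridged)

```
gradient       scheme      e      R      delta_norm  vec_corr
UB1:A    antagonistic  39.09  63.19           28.01     -0.37
UB1:C      concordant 140.91 149.32           22.02      0.99

gradient  modification   ratio
UB1:A     avg_G           1.00
UB1:C     avg_G           0.02
UB1:A     avg_G_sym_B     1.00
UB1:C     avg_G_sym_B     0.00
```

Read: concordant selection on UB1 changes dimorphism (‖Δ‖ = 22.0) almost
as much as antagonistic selection does (28.0), even though it is not
selecting for dimorphism at all — the signature of unequal sex variances
and B asymmetry. Averaging the within-sex blocks leaves the antagonistic
response untouched (ratio exactly 1.00) but collapses most of the
concordant response; removing both asymmetries kills it exactly (0.00).

The same analysis runs end to end from a shell:

```sh
dimorph run-all --scenario table2_like --seed 1 --out-dir out/
dimorph predict-response --g out/g_matrix.csv --out out/responses.tsv
```

which simulates a panel, screens genes, fits the bootstrapped
dimorphism regression, builds PCA traits, estimates the sexed G matrix
(with rank selection and replicate-matrix quantiles) and writes
response/ratio tables plus a manifest with seeds and file hashes.

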