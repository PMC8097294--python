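# Methods

This note records the models, estimators, numerical conventions and
design choices behind `dimorph`, in the order the pipeline applies them.

## Selection-response engine

The core object is a covariance matrix over sexed trait copies, male
block first, shared traits before sex-limited ones within each block.
`B` is stored with male rows and female columns — `B[i, j] = cov(trait i
in males, trait j in females)`; the verbal convention in parts of the
literature is female-first, so the two-trait closed forms name their
cross parameters explicitly (`c12 = cov(M1, F2)`, `c21 = cov(M2, F1)`)
rather than relying on subscript order. All closed forms are verified
against the general engine to 1e-12 in the test suite, which makes the
orientation convention internally consistent whichever verbal convention
a user brings.

Responses carry the factor ½ of the two-sex breeder's equation (each sex
contributes half the autosomal genes). Evolvability `e = βᵀCβ/βᵀβ` and
respondability `R = ‖Cβ‖/‖β‖` follow the standard definitions *without*
that factor; every ratio the package reports (modified/unmodified ‖Δ‖,
A/C comparisons) is invariant to this choice, and absolute response
scales should be interpreted with it in mind. Gradients are normalized
to unit Euclidean norm over the whole sexed vector, so a one-trait
antagonistic gradient is (±1/√2).

The crossover condition d < 2 r_MF/(r_MF² + 1) is implemented exactly as
stated; the helper converting a d-threshold to a variance ratio solves
s² − (2/d)s + 1 = 0 in s = √ρ. (At r_MF = 0.75 this gives a variance
ratio of ≈1.78, at 0.9 ≈1.23; those correspond to standard-deviation
ratios of ≈1.33 and ≈1.11.)

Conditional responses invert the covariance matrix after flooring
eigenvalues at 1e-8 of the largest, and use the conditional evolvability
c(β) = (β̂ᵀC⁻¹β̂)⁻¹, which never exceeds e(β).

Matrix validation: symmetry to 1e-10 relative, eigenvalues ≥ −1e-8·λmax.
Symmetrizing B (and averaging the within-sex blocks) can make the full
matrix indefinite; modified matrices that fail the PSD check are
returned with a warning rather than an error, because the predictions
from them are exactly the point of the modification experiments. A
`bend` utility (clip negative eigenvalues, rescale to preserve the
trace) is available but off by default everywhere.

## Gene-wise pipeline

**Screen.** Per gene, the mixed model has fixed sex (plus probe and
probe×sex for multi-probe genes) and random line, line×sex (plus
line×probe). The likelihood-ratio statistic compares the restricted
likelihood of the full model with the model with all random terms
removed, referred to a plain χ² with 2 df (single-probe) or 3 df
(multi-probe) — no ½χ² boundary mixture, which makes the test
conservative (null retention runs at ~0.2% for the nominal 1%). For the
balanced single-probe design the REML decomposes exactly into
independent contrast classes (within-cell residuals; between-line
sex-sum and sex-difference contrasts of the cell means), giving a
closed-form interior solution with a bounded L-BFGS-B fall-back at the
variance boundaries; unbalanced or multi-probe genes use a generic
per-line-block REML maximized by Nelder–Mead. The balanced path is
checked against statsmodels MixedLM (REML) in the tests and agrees to
four significant figures; the two internal paths agree with each other.

**Line means.** Balanced single-probe cells reduce to replicate means.
Multi-probe genes get probe-adjusted least-squares means: cell
indicators plus sum-coded probe and probe×sex columns, so the cell
coefficient *is* the LS mean (equal probe weighting); verified against a
prediction-averaging normal-equations oracle.

**Summaries.** Between-line (co)variances of line means are reported on
the inbred-line scale as-is — the estimand is the sample covariance
matrix of sex-specific line means, not an outbred G — so they include
the error share σ²_e/R. r_MF is set missing when m·f = 0 and those genes
are dropped from complete-case regressions (counts reported). The
aggregate correlation statistics (r̄w, r̄b, |r̄δw|, |r̄δb|, denominators
2(n−1)) are computed in O(genes × lines) via standardized-matrix row
sums and verified against the brute-force double loop at 1e-10; genes
with zero variance in either sex are excluded with n adjusted. Tissue
specificity uses the standard max-normalized index
τ = Σ_t (1 − x_t/max) / (T − 1); negative (log-scale) inputs are shifted
by the dataset minimum, and transcript-level values are averaged per
gene.

## Dimorphism regression

Response: log10(|D| + 0.01) — the offset tames values near zero, the log
the heavy right tail. Predictors: Ē, τ, log10(ḡ), r_MF, log10|m − f|,
r̄w, r̄b, |r̄δw|, log10(|r̄δb| + 0.01), plus optional 0/1 indicator
columns. Aliased or constant predictors are dropped greedily (later
columns lose) with a record in the results. "Variance explained" per
predictor is the squared semipartial correlation ×100 — the increment in
model R² when the predictor is added last — one of several conventions;
it is documented in the output rather than asserted against any
external table. Inference is a line-level bootstrap: lines resampled
with replacement, line means, D, all G-derived predictors and the
response recomputed per resample, OLS refit; medians and 2.5%/97.5%
quantiles use type-7 interpolation, and an effect is significant when
both quantiles share a sign. Default 1,000 resamples, seed mandatory.

## Trait construction

PCA is on covariance (no variance standardization), centered at the
column means of the observation set, components oriented so the
largest-magnitude loading is positive. Unbiased genes: observations are
the 2L line-sex mean vectors pooled (an L-observation sex-averaged
variant is available via `pooled_sexes=False`); male and female scores
come from the single shared loading set, so a UB trait's dimorphism is
loadingsᵀ(male − female means). Biased classes: dominant-sex line means
only; subordinate-sex scores are deliberately not constructed (those
combinations show no usable genetic variance in this design, and the
default trait set drops them). Default spec: 2 MB + 2 FB + 4 UB
components → 12 sexed variables, 4 shared.

## G estimation and uncertainty

The estimator is deliberately simple and closed-form rather than an
iterative reduced-rank REML fit: with S_B the covariance of line means
(L−1 df) and S_W the pooled within-line covariance (L(R−1) df), the
between- and within-line scatters are modelled jointly as Wisharts with
expectations G_r + Σ_W/R and Σ_W. In the basis diagonalizing S_B against
S_W/R the profile restricted likelihood separates per coordinate and the
rank-r maximum keeps max(λ_i, 1) − 1 on the top-r generalized
eigenvalues (mapping back through (S_W/R)^½), zero elsewhere — PSD by
construction. Profiling Σ_W rather than plugging it in matters: it stops
sampling noise in the junk dimensions from masquerading as genetic rank.
Rank is selected by AICc with r·d − r(r−1)/2 genetic parameters (the
error parameters are common to all candidates) and the small-sample
correction taken at the scalar degrees of freedom n = (L−1)·d; on
planted rank-3 data in 8 dimensions at 200 lines the correct rank is
selected in ≥90% of simulations, and the 12-trait reference matrix is
recovered to <15% relative Frobenius error at 400 lines × 2 replicates.
With no replication the estimator degrades to the raw line-mean
covariance with a warning.

Uncertainty propagation redraws S_B and S_W from central Wisharts at the
estimated parameters and degrees of freedom, re-applies the estimator
(subtraction, PSD projection, truncation to the selected rank) to each
draw, and summarizes any scalar functional of G by its median and
2.5%/97.5% quantiles over (by default) 1,000 replicates. This is a
parametric stand-in for sampling from the asymptotic distribution of a
REML fit; both method tags are recorded in the results and the pipeline
manifest.

## Synthetic panels

The generator reproduces the study design it emulates: 40 lines, 2
sexes, 2 replicate chips, three bias classes sized 150 (MB), 200 (FB)
and 700 (UB) — scaled down about tenfold from the motivating data set so
the full pipeline runs in minutes on one CPU; the line/replicate
dimensions are kept at full scale because they, not the gene count,
drive the statistics. Per gene, ḡ is log-normal (median 0.1 on the
squared-log2 scale), log10(m/f) is normal with class-specific mean
(±0.7 for biased classes, mimicking the dominant sex holding the
variance), r_MF is a clipped normal, and chip noise has σ = 0.25 log2
units. Cross-gene genetic correlations come from class-private line
factors with controllable cross-sex factor correlation and male/female
loading similarity; each gene's factor share plus an idiosyncratic 2×2
Cholesky remainder reproduces its planted (m, f, b) exactly (the
cross-sex remainder is clipped into the PSD cone, and the truth table
records realized values). Named scenarios: `null` (zero genetic
variance, for screen calibration), `sas_architecture` (|D| coupled to
1 − r_MF), `scs_architecture` (|D| coupled to log10|m − f|), and
`table2_like` (block factors giving a 12-trait layout whose four shared
factors have cross-sex correlations 0.60, 0.95, 0.74, 0.99 — mean 0.82).

A constructed 12-trait reference matrix (`table2_reference_g`) serves as
ground truth for estimator tests and as the worked example. It is
synthetic: built as ΛΛᵀ + diag with the shared-trait factors the only
contributors to the B diagonal (pinning the four r_MF values exactly,
averaging 0.82 with three near 1), single-sex factors providing
within-sex correlation structure, and cross-sex factors on disjoint
trait sets providing B asymmetry.

What the generator does *not* emulate: probe-level microarray artifacts,
normalization effects, heavy-tailed line effects, relatedness among
lines, and cross-class genetic correlations. Passing tests therefore
demonstrate correctness of the estimators under a Gaussian, balanced,
unrelated-line design — the same assumptions the mixed models make —
not robustness to violations of it.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale sizes chosen to keep the whole
suite around a minute: 1,050-gene panels for screen calibration and the
architecture regressions (200 bootstrap resamples there, against the
1,000 default), 400 null genes per calibration batch in unit tests,
10–20 simulations for rank and Frobenius recovery, and 1,000 random
matrices for the symmetrization theorems. Closed-form/engine agreement
is asserted at 1e-12 absolute; exact structural ratios (antagonistic
averaging → 1, concordant joint symmetrization → 0) at 1e-10; quantile
computations use numpy's default type-7 interpolation throughout.

## Known limitations

* The screen's χ² referral is conservative at the variance boundary;
  power comparisons against a boundary-corrected mixture are not
  implemented.
* The moment/profile G estimator assumes a balanced design with the same
  replicate labels in both sexes; unbalanced trait-score designs are
  rejected rather than approximated.
* Wishart resampling captures sampling noise of the balanced two-matrix
  design, not the full REML information geometry; intervals for
  near-boundary eigenvalue functionals will be approximate.
* Absolute scales of e, R and ‖Δ‖ depend on the trait scaling the PCA
  produces; only ratios are scale-free.
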