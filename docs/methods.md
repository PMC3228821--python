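# Methods

This note records the statistical model behind `icaqtl`, the defaults and
why they were chosen, the design decisions taken where the procedure was
genuinely open, and what the synthetic-data experiments do and do not
establish.

## Model and assumptions

Gene expression is modelled as a linear mixture of a small number of latent
processes: `x_ij = Σ_k s_ik a_kj + ε_ij`, with signatures `s_·k` (gene
loadings) assumed sparse and supergaussian — most genes near zero, a
distinct tail of strongly co-regulated genes — and patterns `a_k·`
(per-individual activations) free to correlate with one another. ICA
estimates the rotation of the dominant SVD subspace that makes the
signatures maximally non-Gaussian; the sparsity assumption is what ties a
component to an interpretable gene *module*. A *trans*-acting variant is
modelled as an additive dose effect on a pattern, possibly mediated by
*cis* effects on one or two genes at the locus.

Assumptions worth keeping in mind: linearity of mixing, approximate
independence of signatures across genes, and genotype effects that are
shared across the module rather than concentrated in one transcript (the
two-step association test is designed precisely to enforce the last point).

## Preprocessing

* Probe→gene collapsing averages probes on the raw intensity scale, before
  any transform.
* The detection filter keeps a gene when the fraction of samples with
  detection p < 0.05 is significantly above the 5% chance rate by a
  one-sided **exact** binomial test at α = 0.05. The test's α is not fixed
  by convention anywhere authoritative; 0.05 one-sided is the default and
  both α and the null rate are configurable. The exact test was chosen over
  a normal approximation because cohort sizes in the hundreds put the
  interesting genes near the boundary where the approximation is worst.
* arcsinh(x) = ln(x + √(x²+1)) stabilizes variance across intensity levels
  while accepting zero and negative background-subtracted values, where a
  log transform would fail.
* Standardization is per gene, mean 0 / variance 1 with the n−1 denominator
  (used consistently here and in the ANOVA sums of squares).

## Outlier screening

Expression arrays are compared by d = 1 − |Pearson r| over genes; genotype
samples by 1 − IBS (mean shared-allele fraction). Classical (Torgerson)
MDS embeds each distance matrix; samples whose per-axis robust z-scores
(median/MAD) exceed `k_mad = 6` in Euclidean norm are flagged, the
embedding is recomputed on the survivors, and the loop runs at most 3
rounds. The reference procedure this emulates excluded outliers by visual
inspection over repeated MDS runs; a deterministic robust-distance rule
replaces eyeballing because reproducibility requires one. `k_mad` is a free
parameter: 6 flags only gross structure (mixed-up samples, ancestry
outliers) and leaves a homogeneous Gaussian cloud untouched at n = 500.

## Number of components

The scree of the standardized matrix is compared against a null obtained by
permuting every gene's values independently across samples — this preserves
each gene's marginal distribution and destroys covariance. The null must be
corrected for variance already claimed by accepted components. We implement
the correction by **deflation**: when component *s* is accepted, its rank-1
SVD term is subtracted and both the next observed eigenvalue and its
permutation null are computed on the residual. An earlier variant that
rescaled the original null curve by the unclaimed-variance ratio was found
to bias the null low whenever a minority of genes carries most of the
signal (the residual is then strongly heteroskedastic across genes while
the rescaled null keeps every gene at unit variance), inflating K severely
on sparse synthetic signal; permuting the residual makes the null inherit
the residual's per-gene variances and removes the bias.

A component is accepted while its observed top eigenvalue exceeds the null
by a relative margin of 0.05. The margin covers the Monte-Carlo fluctuation
of a single-permutation null: on pure-noise matrices (1000×200) the
observed/permuted top-eigenvalue ratio fluctuates with sd ≈ 1.5–2%, so 5%
is roughly a 3-sigma guard and a structureless matrix yields K = 0, while
genuine components in the regimes of interest exceed their null several
fold. `n_perm > 1` averages null draws.

## ICA

Whitening is the truncated SVD of the standardized matrix itself (genes act
as observations), so the extracted components live exactly in the rank-K
subspace and `S A` reproduces the rank-K projection of X to machine
precision. The symmetric (parallel) fixed-point iteration maximizes the
logcosh negentropy proxy with α = 1, tolerance 10⁻⁴, at most 200
iterations. Ten restarts are run from seeds `seed+0 … seed+9` and the
converged run with the largest summed negentropy proxy is kept; the winning
restart index is recorded. Determinism: identical inputs and seed give
bitwise-identical output. Sign indeterminacy is resolved by orienting every
signature to non-negative skewness; scale indeterminacy by unit-variance
signature columns, with A absorbing magnitudes.

Component filters: a pattern in which one individual contributes strictly
more than 10% of the sum of squared deviations is "individual-specific" and
dropped regardless of kurtosis; remaining signatures need excess kurtosis
≥ 3. Whether the kurtosis cutoff is meant on the raw scale (Gaussian = 3)
or the excess scale (Gaussian = 0) is ambiguous in the source description;
**excess** is the default here because it makes the filter a genuine
non-Gaussianity requirement (a Gaussian signature scores 0 and fails), and
`kurtosis_scale="raw"` is available.

## Module definition

Each signature's loadings are treated as z-scores from a two-group mixture.
The null Gaussian is fitted robustly: centre = median; scale = maximum
likelihood of a truncated Gaussian using only the loadings inside the
central 75% quantile window (the tails never enter the fit); null
proportion η₀ = observed window fraction / null window mass, clipped to
(0, 1]. The estimator is unbiased in simulation with sampling sd ≈ 3% of
the true scale at 10⁴ genes — adequate, since membership decisions depend
on far-tail z-scores. Membership: the primary rule thresholds the
monotonized tail-area FDR (q-value), q < 10⁻³; a plain null tail
probability rule (`rule="null_p"`) is available because the source
description uses "probability < 10⁻³ under the null" and "FDR < 10⁻³"
interchangeably. Membership is two-sided and invariant to affine rescaling
of the loadings.

Gene-set enrichment is the exact hypergeometric upper tail against the
analyzed-gene universe; sets smaller than 5 after universe intersection are
not tested and do not count toward the Bonferroni family, which stabilizes
the family size against junk sets.

## Association

SNP QC drops variants with MAF < 0.01, exact-HWE p < 10⁻⁴, or call rate
< 0.95 (cutoffs unstated in the source; these are conventional GWAS values
and configurable). The HWE test is the exact conditional test on the
heterozygote count. Association is a one-way fixed-effects ANOVA with
genotype as a **categorical** factor: 2 d.f. with all three classes,
automatically 1 d.f. when a class is absent; missing genotypes are dropped
pairwise, never imputed. R² is SS_between/SS_total from the same
categorical model (an additive-coding R² would be slightly smaller for
non-additive patterns; the categorical one matches the test actually
performed). Step-1 suggestive threshold 10⁻⁷; step-2 per-gene threshold
10⁻⁵ with the **full post-preprocessing gene set** as the enrichment
universe; study-wise enrichment threshold α/(n_modules · n_snps), reported
with the mantissa truncated to three significant digits.

Mediation: the cis-mediation check residualizes both the trans expression
and the genotype-class indicators on the mediator expressions and reports
the partial R² of genotype; full mediation collapses it toward zero while
mediator-independent effects leave it unchanged.

## Contamination surrogates

Cell-type-specific genes are those over-expressed with fold change strictly
> 2 in one lineage versus the best competing lineage (linear-scale
reference means); a gene joins at most one list. Surrogates are per-sample
means of the listed genes' **arcsinh-scale** values, computed before gene
standardization — standardizing first would erase exactly the
between-sample level differences the surrogate must capture. Expression is
never pre-adjusted before ICA (such adjustment can induce artefactual
correlations because "specific" genes are often weakly expressed in the
target cells too); adjustment is post hoc: each significant SNP-pattern
association is re-tested with all surrogates as covariates, and "lost
significance" is judged against the step-1 threshold 10⁻⁷ (configurable, no
explicit criterion exists in the source).

## Replication

A module-SNP association replicates in an independent cohort when (1) at
least two module genes pass 0.05 Bonferroni-corrected for the **full module
size** (even when fewer genes were measurable), and (2) the count of
nominal 0.05 hits beats the 5% chance rate by a one-sided exact binomial
test at 0.05. Optional covariates (age, sex, centre) are residualized out
of expression before the per-gene ANOVA. Proxy-SNP substitution is the
caller's responsibility.

## Synthetic data

The generator plants exactly the structure the analysis assumes: disjoint
gene modules with loadings ±`loading_effect` (random sign, 10%
multiplicative jitter — supergaussian by construction) against
`N(0, background_sd²)` background loadings; unit-variance activation noise
plus an additive dose effect scaled analytically via Var(dose) =
2·maf·(1−maf) to hit the target pattern R²; direct cis effects on the first
`n_cis_per_component` module genes, sign-aligned with the gene's loading
and sized to roughly half the gene's variance (mimicking strong cis eQTLs
like those that mediate real trans clusters); optional contamination adding
cell-type profiles weighted by per-sample |N(0, fraction_sd)| fractions
truncated at 0.5; iid Gaussian measurement noise. One global seed spawns
independent per-purpose streams (genotypes, loadings, activations, noise,
contamination).

Defaults — 2000 genes × 300 samples, K = 3 modules of 50 genes,
`loading_effect = 3`, `background_sd = 0.1`, `noise_sd = 1`, one driver SNP
at R² = 0.2, MAF 0.3 — represent a desk-scale cohort with a trans effect in
the upper-middle of the 2–25% range seen for real lead SNPs.
`background_sd` is deliberately an order of magnitude below `noise_sd`: in
real data a non-member gene's variance is dominated by its own biological
and technical noise, not by weak coupling to other modules. If the
background is made comparable to the noise, per-gene standardization
flattens the signatures into bimodal, *sub*gaussian shapes and the kurtosis
filter correctly rejects everything — a useful reminder that the sparsity
assumption is about loadings *relative to per-gene variance*.

What the simulator does **not** model: probe-level artefacts and
cross-hybridization, LD between SNPs (one causal SNP per component), batch
or array effects, non-linear regulation, and overlapping modules. Passing
the recovery tests therefore demonstrates correctness of the machinery
under the model's own assumptions, not robustness to everything real
cohorts contain.

## Numerical choices and degenerate inputs

* ICA convergence: max row-wise |cos| deviation < 10⁻⁴; non-convergence of
  every restart raises with per-restart diagnostics.
* Kurtosis uses population moments (m₄/m₂² − 3, no bias correction); ±1
  two-point data give exactly −2.
* Zero-variance genes must be dropped before standardization (the pipeline
  does this and logs the count); zero-variance patterns/surrogate columns
  are invalid/dropped with warnings.
* MDS axes with zero MAD are skipped in outlier flagging; negative
  eigenvalues are excluded from embeddings.
* Rank-deficient adjusted designs fall back to least-norm fits with a
  warning; empty genotype classes reduce degrees of freedom rather than
  invalidating the SNP.
* All tabular output uses 12 significant digits and round-trips losslessly
  at that precision.

## Problem sizes used in the test-suite experiments

Simulated experiments run at 1000–2000 genes × 200–300 samples with 10–20
replicate seeds, and 10⁴ replicates for null-calibration checks — sizes at
which every property being tested (eigenvalue separation, module FDR
behaviour, two-step association power at R² = 0.2) is already in its
asymptotic regime, while the whole suite stays fast enough to run routinely.

## Known limitations

* With very small K the ICA rotation is only as identifiable as the sources
  are non-Gaussian; two near-Gaussian components may come out mixed.
* The empirical-null scale estimator's ~3% sampling noise slightly blurs
  module boundaries for genes sitting exactly at q ≈ 10⁻³.
* The deflation scree rule tests components sequentially; a weak component
  hiding behind an accepted one of equal eigenvalue is found only after
  deflation, so ordering effects are possible at exact eigenvalue ties.
* The contamination label is threshold-based, not a formal mediation test;
  an association can "lose significance" through power loss alone if the
  surrogates are highly collinear with a genuine pattern.
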