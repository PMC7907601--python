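# Methods

This note records the models `phenogs` fits, the estimands it reports,
the numerical choices that matter, and what the synthetic data do and do
not establish.

## Trial adjustment

Plot values from an augmented complete block design are adjusted per
environment with the fixed-effects model

    y_ij = mu + block_i + check_j + e_ij,

fitted on the check plots only (they carry all the between-block
information), with sum-to-zero constraints on block and check effects.
An unreplicated entry's BLUE is its observation minus the estimated
block deviation; a check's BLUE is the mean of its block-adjusted
observations.  This single additive correction per block preserves
within-block rankings by construction.  Blocks without checks are a hard
error (the block effect is inestimable), as are duplicated unreplicated
entries.

Broad-sense heritability uses the same layout with genotypes random and
mean + block fixed, H2 = sigma2_g / (sigma2_g + sigma2_e) on a plot
basis, clamped to [0, 1].  H2 from a mostly-unreplicated augmented
layout is intrinsically noisy — only the checks separate sigma2_g from
sigma2_e — and estimates on such layouts should be read accordingly; the
estimator itself is verified on properly replicated simulated designs
(200 genotypes x 2 blocks recovers 0.5 +/- 0.05 over 20 seeds).

## Single-trait REML

For y = X beta + g + e with g ~ N(0, K sigma2_a): the restricted
likelihood is evaluated on error contrasts.  X is QR-completed to an
orthonormal basis, K is rotated into the complement of span(X), and the
rotated kinship is eigendecomposed; the likelihood is then a smooth 1-D
function of delta = sigma2_e/sigma2_a, maximized by a 64-point grid on
log delta in [-10, 10] followed by bounded Brent refinement (tolerance
1e-8), so the optimum can never fall below the best grid point.  (A
common shortcut — eigendecomposing SKS with S the projection matrix and
keeping the top n-p eigenvectors — silently mixes fixed-effect
directions into the contrast space when K is rank deficient, e.g. for a
genotype-incidence kinship with replication; the explicit basis avoids
this.)  Estimates at the search boundary are flagged, not errored; an
exactly-zero residual variation after projection is a hard error.

## Heritability estimands

Two ratios are reported deliberately differently:

* `VarianceComponents.h2` is the plain component ratio
  sigma2_a / (sigma2_a + sigma2_e) on the scale of the supplied kinship.
* `quantgen.narrow_sense_h2` reports genomic heritability on the sample
  scale: the genetic variance is sigma2_a x (tr G - 1'G1/n)/(n-1), the
  expected sample variance of genetic values per unit component.  In
  panels of inbred, family-structured lines the VanRaden G has mean
  diagonal well above one (about 1.9 in the simulated NAM panel), and
  without this conversion the component ratio understates the variance
  fraction realized among the study lines by roughly 0.1.  Genetic
  correlations are ratios of H entries and need no such conversion.

## Multi-trait model

The multi-trait GBLUP stacks t traits with per-trait intercepts,
g ~ N(0, H ⊗ G) and e ~ N(0, R ⊗ I), H and R unstructured.  H and R are
estimated by EM-REML on lines with complete records; the EM runs in the
eigenbasis of G, where the mixed-model equations become an arrow matrix
(one t x t block per eigenvalue plus the fixed-effect block), giving
O(n t^3) per iteration after one O(n^3) eigendecomposition.  The updates
are the classical MME-inverse EM formulas and are algebraically
identical to the unrotated form; the restricted log-likelihood is
monotone along the path and convergence is declared at relative change
below 1e-6 (cap 500 iterations; non-convergence returns the last iterate
with a warning).  H and R are eigenvalue-clipped at 1e-8 whenever an
update leaves the PSD cone.  A single-trait call short-circuits to the
univariate spectral REML path, exactly.

Prediction solves the conditional BLUP over *all* observed cells —
including lines observed only for secondary traits.  This is the
mechanism that transfers index information into the primary-trait GEBV
of unharvested lines: the covariance between a line's unobserved primary
genetic value and its observed index records is H ⊗ G restricted to
those cells.  Test lines' primary phenotypes never enter estimation or
prediction.  Traits with no observed cells get no intercept and their
GEBVs are reported centered.

## Cross-validation

Five folds, lines shuffled per replicate from a dedicated child seed;
two sets of fifty replicates by default.  Within a replicate the fold
predictions are pooled and a single Pearson r against the observed
values is computed; the mean and standard error are taken across
replicates.  Pooled predictions are fold-centered first: each fold's
model carries its own baseline, and without alignment those offsets are
anti-correlated with the held-out fold means, which shows up as a
structural negative "accuracy" of about -0.07 for a trait with zero
heritability.  With fold-centering a null trait calibrates to zero
within sampling error (mean -0.02, sd 0.05 across independent
datasets).  Per-fold aggregation (mean of within-fold correlations) is
available via `CVConfig.aggregate="fold"`.

Replicate accuracies within one dataset are strongly correlated — they
reuse the same lines — so the across-replicate standard error describes
fold-assignment noise only, not dataset-level sampling.  Calibration
claims are therefore made on means over independent simulated datasets.

Across-environment validation trains variance components and fixed
effects in one environment and predicts another: the univariate model
correlates the training-environment GEBVs with the test-environment
values; the joint models additionally condition on the test
environment's indices (the "spectra collected, plots not harvested"
scenario).  Line sets are intersected with a logged count when they
differ.

## Synthetic data

The generator inverts the model the analysis assumes, with one named
substream per stage (genotypes / effects / residuals / layout /
reflectance) derived from a single root seed.

* **Genotypes.** One common parent crossed to each founder; founder
  alleles i.i.d. Bernoulli with locus frequencies ~ U(0.1, 0.9); RILs
  advanced by five generations of selfing with Poisson crossovers under
  a Haldane map.  Residual heterozygosity matches the single-locus
  Markov-chain expectation (0.5^g per initially heterozygous locus).
  Landrace LD structure, selection during population development, and
  epistasis are deliberately not emulated: QC, GRM and REML behavior is
  under test, not LD fine-structure.
* **Traits.** Marker effects are multivariate normal across traits with
  the requested genetic correlation; each trait's effect column is
  rescaled so the realized breeding-value variance is one, and
  per-environment residuals with variance (1-h2)/h2 and the requested
  residual correlation deliver the target heritability.  Genetic values
  are shared across environments; no genotype-by-environment interaction
  is modeled.
* **Field layout.** Entries appear once per environment; a fixed set of
  named checks appears in every block, at least two per block.  Block
  effects (sd 0.5) and plot errors (sd 0.2) are expressed as multiples
  of each trait's within-environment phenotypic SD among entries: the
  environment-level residual drawn by the trait simulator already
  represents non-genetic variation at the adjusted-mean level, so the
  plot error is the additional within-block measurement noise the
  design removes imperfectly.
* **Reflectance.** A green-canopy baseline across 16 bands
  (430–970 nm) is perturbed along latent physiological axes — greenness
  (680/780/800), water (970), pigments (531), plus dedicated 430 and
  700 nm axes — by the standardized latent index targets, with small
  i.i.d. band noise and a floor of 0.01 so ratio indices stay bounded.
  Indices recomputed from the emitted spectra correlate above 0.9 with
  their latent targets; the default simulated trait set carries one
  index per axis (NDVI, NWI, PRI) so no two targets compete for a band.
  All eight indices are still computable from every spectrum.

Because the generator and the analysis share the same model family,
passing recovery tests demonstrates internal consistency and correct
implementation, not robustness to model misspecification (LD structure,
non-additive variation, spatial field trends, spectral nonlinearity).

## Problem sizes and defaults

Parameter recovery runs 20 panels of 500 lines x 2,000 markers
(heritability within +/-0.05 and genetic correlation within +/-0.10 of
the realized truth, as means over panels).  The multivariate-advantage
benchmark uses 600 lines, 2,000 markers, primary h2 = 0.3, secondary
h2 = 0.8, r_G = 0.7, and fifty cross-validation replicates; at these
sizes the whole acceptance script completes in a few minutes on one
CPU.  QC thresholds default to the conventional 20% marker / 10% line
missingness and MAF 0.10 (markers at exactly 0.10 are kept); GRM
eigenvalues are floored at 1e-8 so a Cholesky factorization always
succeeds; division guards set an index missing (never infinite) when a
denominator band falls below 1e-9; reflectance read as percent is
normalized to fractions when the panel maximum exceeds 1.5.

## Known limitations

* H2 from real augmented layouts is check-limited (see above).
* EM-REML is first-order: near-boundary genetic correlations (|r_G|
  close to 1) converge slowly and are clamped with a flag when they
  overshoot numerically.
* The across-environment validation shares lines between training and
  test environments (the panel is the same physical population), so it
  measures transfer of environment-specific information, not prediction
  of unseen germplasm.
* No spatial modeling beyond blocks, no Bayesian shrinkage-family
  models, no genotype-by-environment covariance structure.
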