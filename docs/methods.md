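# Methods

`megblup` implements the standard two-stage analysis of replicated
multi-environment plant breeding trials, followed by GBLUP genomic
prediction under three cross-validation schemes, together with a
synthetic trial generator that makes every stage verifiable against a
known truth. This note documents the models, the estimation machinery,
the generator's assumptions, the numerical choices, and the known
limitations.

## Stage-1 trial models

Plot-level data are analyzed with two random-effects models, fitted by
REML with the grand mean `mu` as the only fixed effect (a model with no
fixed part is degenerate; the mean is fitted fixed even though every
other term is random):

- within one environment: `y_ik = mu + Rep_i + Gen_k + e_ik`
- across environments:
  `y_ijk = mu + Env_i + Rep_j(Env_i) + Gen_k + (Env x Gen)_ik + e_ijk`

All random terms carry identity kernels. Entry-mean broad-sense
heritability is computed from the REML components as

    H2_within = s2_g / (s2_g + s2_e / nReps)
    H2_across = s2_g / (s2_g + s2_ge / nEnvs + s2_e / (nEnvs * nReps))

Estimates are kept at full precision internally and rounded (2 decimals)
only in reports. Negative component estimates cannot occur: the REML
optimizations are constrained to the nonnegative orthant (boundary
solutions are reported as exact zeros), which keeps both H2 formulas in
[0, 1].

Genetic correlations between traits are Pearson correlations among
across-environment genotype BLUP vectors (the convention of the META-R
lineage of trial-analysis tools); phenotypic correlations are Pearson
correlations among raw genotype means. Full bivariate REML is out of
scope. Note a consequence of these definitions: on *balanced* data the
genotype BLUP is a shrunken genotype mean, so the BLUP-based and
raw-mean correlations coincide; both are attenuated below the true
genetic correlation by the factor `H2_entry-mean` of each trait. The
two tables diverge only on unbalanced data.

Trait PCA is performed on the centered, unit-scaled genotype-by-trait
BLUP matrix (constant columns dropped with a warning; missing cells
mean-filled); explained variances are the eigenvalues of the correlation
matrix expressed as percentages.

## REML engines

Four solvers cover the designs that occur in the pipeline; each is exact
REML on its domain and they are cross-checked against one another in the
test suite.

**Spectral single-kernel solver.** For `y = Xb + Zu + e`,
`u ~ N(0, s2_g K)`, the restricted likelihood is profiled to a 1-D
search over `lambda = s2_e/s2_g` in the eigenbasis of `ZKZ'`, solved by
bounded scalar minimization on `log lambda in [-10, 10]` (tolerance
1e-10). BLUPs at the optimum are exact and cover unphenotyped kernel
levels through their covariances — the mechanism by which untested lines
are predicted. This solver is the GBLUP/ridge-regression equivalence
made explicit, and the test suite asserts the equivalence numerically.

**EM-REML multi-kernel solver.** For arbitrary (unbalanced) designs
with several random terms, expectation-maximization updates of each
variance component. EM is slower than average-information updates but
unconditionally stable at the problem sizes used here (hundreds of
records), and its restricted likelihood is non-decreasing by
construction — asserted per iteration in tests. Convergence: largest
relative component change < 1e-6 (default) or 500 iterations, in which
case the best iterate is returned flagged `not converged`. EM approaches
zero-variance boundaries slowly; estimates near a boundary are accurate
in likelihood long before formal convergence.

**Balanced-strata solver.** A balanced crossed design with identity
kernels decomposes into orthogonal strata with diagonal covariance
(classical ANOVA strata). REML then minimizes
`sum_s d_s log v_s + SS_s / v_s` with `v_s` linear in the components —
a few-parameter bounded optimization solved from the method-of-moments
start. This path is exact, costs microseconds independent of line count,
and supplies Fisher-information standard errors
(`I_jk = 1/2 sum_s d_s A_sj A_sk / v_s^2`). The trial-model functions
use it whenever the data form a complete grid and fall back to EM-REML
otherwise, handling missing plots natively (no plot deletion).

**Spectral G×E solver.** The multi-environment GBLUP model

    y_ij = E_i + g_j + gE_ij + e_ij,
    g ~ N(0, s2_g G),  gE ~ N(0, s2_ge I (x) G)

with fixed environment intercepts is fitted on complete
line-by-environment grids by simultaneous diagonalization: both random
covariances are diagonal in (environment mean/contrast basis) (x)
(eigenvectors of G), so each likelihood evaluation is O(n) and the
three variance parameters are found by direct optimization (Nelder-Mead
on log-variances, three starts). Every cross-validation training set in
this package is a complete grid (CV1 masks whole lines, CV2 masks a
whole environment), so this exact path is always applicable there; it
agrees with the EM solver to numerical tolerance in tests. Environment
enters as a fixed intercept: with four levels a random environment term
adds nothing, and the accuracy metric is location invariant.

All genomic kernels receive a `1e-6` diagonal shrinkage when the GRM is
built, guaranteeing invertibility inside the engines.

## Genotypes, QC and the GRM

Dosages are minor-allele counts in {0, 1, 2} with NaN for missing.
Readers: plain TSV matrix (with a marker-map sidecar: marker,
chromosome, position in Mb, 1-based), VCF (biallelic records only;
multi-allelic sites dropped with a logged count; POS converted from
1-based bp), and HapMap-style tables with IUPAC single-letter codes.

QC applies, in order: samples at call rate > 0.8, markers at call rate
> 0.7, markers at MAF >= 0.05 — MAF computed on the surviving samples,
which is why samples are filtered first; the order is recorded in the
QC report. Missing calls are imputed by the per-marker mean (default)
or mode. A haplotype-based imputer is deliberately not used: at
post-QC missingness the naive fill has negligible effect on the GRM,
and it keeps the pipeline free of external binaries. This is a
documented divergence from GBS practice that matters only at high
missingness.

The GRM is the first VanRaden construction with observed allele
frequencies, `G = WW' / (2 sum p(1-p))`, `W = M - 2p`, plus the `1e-6`
diagonal shrinkage. It is invariant to marker order and to flipping the
allele coding of any marker, and for an unstructured panel its diagonal
averages ~1 (the grand sum of G is exactly zero because W is
column-centered, so the off-diagonal mean sits at `-mean(diag)/(n-1)`).

## Cross-validation schemes

The response for every prediction model is the stage-1 per-environment
adjusted value (`mu + genotype BLUP` from the within-environment model);
raw plot data never enter the prediction stage. Accuracy is the Pearson
correlation between predictions and the observed adjusted values of the
validation set; undefined correlations (fewer than 3 test lines, zero
variance) are recorded as missing, never as zero.

- **SE_CV1**: per environment, k-fold CV (default 5 folds x 50 repeats)
  of the single-kernel GBLUP model.
- **ME_CV1**: the same fold protocol, masking each fold's lines in all
  environments simultaneously; predictions for masked cells are
  `E_i + g_j + gE_ij`. The repeat count matches SE_CV1 for
  comparability.
- **ME_CV2**: deterministic leave-one-environment-out. The held-out
  environment's intercept and interaction are unestimable from the
  training data, so predictions are the main genetic BLUPs alone;
  Pearson accuracy is location-scale invariant, so the missing
  intercept is immaterial.

Folds are equal-sized up to one line (141 lines -> 29+28+28+28+28), and
repeat-specific fold seeds are spawned from the master seed, making an
entire CV run bit-for-bit reproducible from (data, master seed).
Training and validation sets are asserted disjoint at every fit.

## The synthetic trial generator

A plot value is `y_ijk = env_mean_i + g_j + gE_ij + eps_ijk`. The
additive value `g` is a linear combination of `n_qtl` randomly chosen
markers with i.i.d. normal effects, rescaled post hoc so the realized
sample variance of `g` equals `var_g` exactly (so heritability targets
hold in expectation without Monte-Carlo slack on the genetic side). The
interaction `gE` is i.i.d. normal per (line, environment) — a
compound-symmetric G×E, independent across environments like the
`I (x) G` structure the prediction model assumes, but unstructured
across lines. `eps` is i.i.d. per plot. Genotypes are unlinked
biallelic SNPs in Hardy-Weinberg proportions with allele frequencies
uniform on `maf_range` and positions uniform along the chromosomes.

Default dimensions emulate the motivating wheat panel: 141 lines,
14,563 SNPs on the 21 bread wheat chromosomes (~14,000 Mb total), four
environments (two locations x two years), two replicates. Trait presets
carry the published across-environment variance components (e.g., grain
yield 0.05/0.15/0.33 in (t/ha)^2, days to heading 8.94/2.29/3.74 in
days^2) and per-environment means. The trait's genetic architecture is
not published; presets default to `n_qtl = 300` (a polygenic but not
fully dense architecture) and expose the knob.

**What the generator does not emulate — and what that implies.** There
is no linkage disequilibrium, no pedigree or population structure, no
dominance/epistasis and no spatial field trend. Unrelated lines make
marker-based prediction of *new* lines much harder than in the real
panel, where relatedness drives accuracies of 0.7+. Consequently the
scheme comparison on simulated data reproduces the *ordering*
(multi-environment models dominate the single-environment baseline, and
leave-one-environment-out prediction of tested lines is strong when
environments are genetically correlated) but not the published
magnitudes, and it does **not** reproduce the equivalence of ME_CV1 and
ME_CV2 observed on the real panel: predicting untested lines (bounded
by marker-equation information, here r ~ 0.1-0.2) and predicting tested
lines in an untested environment (driven by each line's own records,
here r ~ 0.5-0.7) only coincide when strong relatedness lifts new-line
accuracy — precisely the feature this generator omits. The
corresponding acceptance assertion is kept as stated and fails on this
generator; passing tests therefore certify the estimators and the
scheme ordering, not real-panel accuracy levels.

## Scenario presets used in the comparison studies

The scheme-comparison scenarios fix `var_g/var_ge = 2` or 4 with
within-environment entry-mean heritability ~0.6 and ~0.78
(`gxe-moderate-h2`: 1.0/0.5/2.0; `gxe-high-h2`: 1.0/0.25/0.7) on a
141-line x 2,000-marker panel; comparisons are paired per seed (shared
data and fold sequences) over 30 seeds with 5-fold x 5-repeat CV, and
differences are judged by sign tests. Component-recovery studies use
500 lines so that Fisher-information standard errors are in their
asymptotic regime; coverage is checked with 95% sampling bands
(`+/- 1.96 SE`), the conventional definition of "recovered within
sampling error" — a one-SE band would by construction cover only ~68%
of calibrated replicates.

## Numerical choices and degenerate inputs

- `lambda` search bounds `e^-10..e^10`; EM tolerance 1e-6, 500
  iterations; strata/G×E optimizers run to 1e-9..1e-12 tolerances.
- Kernels must be PSD up to `-1e-8` relative; the GRM shrinkage makes
  this hold in practice.
- The mixed-model-equation solve used for BLUPs floors the residual
  variance at `1e-8 * var(y)` purely for conditioning in the noiseless
  limit (components themselves are not floored).
- Zero-variance terms are dropped from the BLUP solve (their BLUPs are
  exactly zero).
- A single training environment in the G×E model leaves `s2_g` and
  `s2_ge` unidentifiable (their sum is identified); this occurs only in
  ME_CV2 with two environments and is flagged with a warning.
- Heritability with an all-zero denominator raises an error rather than
  returning a value.
- The strata likelihood differs from the dense restricted likelihood by
  the constant `0.5 log n`; reported log-likelihoods are on the dense
  scale so the engines are directly comparable.

## Known limitations

- Naive imputation (documented above); no haplotype phasing.
- Genetic correlations are BLUP-based, not bivariate REML, and are
  attenuated by entry-mean noise.
- The generator's missingness is uniform at random — sufficient for
  call-rate filters, not a model of real GBS missingness.
- EM-REML standard errors are not computed on the unbalanced path
  (balanced fits report Fisher-information SEs).
- No LD, structure, dominance or spatial trends in the generator; see
  above for the consequences.
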