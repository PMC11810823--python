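# Methods

## Simulation model

The generator emulates a recurrent-testing scheme for feather score (FS).
A closed sire line is bred for `pedigree_depth` generations (default 4):
generation 0 holds unrelated founder males and females, every later animal
draws both parents at random from the previous generation (full sibs and
mild inbreeding arise naturally), and the terminal-generation males are
the test sires. Each test sire receives `daughters_per_sire` = 53
crossbred daughters with unknown dams, split over `cages_per_sire` = 6
cages by a multinomial draw repaired into the 3–22 bird range, matching
the design constants of the motivating scheme (d = 20 dams, n = 53 daughters, m = 6
cages per sire).

Per daughter and per trait (BACK/NECK at 45/70 weeks) a Gaussian liability

    L = f(batch) + f(farm x date x cross) + f(gene) + s(sire) + c(cage) + e

is generated, with sire transmitting abilities `s ~ N(0, sigma2_S A)`
simulated by gene dropping through the sire pedigree (parent average plus
a Mendelian term scaled by the Meuwissen–Luo within-family variance, so
the effects have covariance exactly `G0 ⊗ A`), independent cage effects
and per-trait residuals. Dams are never identified, so the dam and
Mendelian-sampling variation (¾σ²_A) is absorbed into `sigma2_e`; the
animal-scale additive variance is by construction σ²_A = 4σ²_S. The four
FS traits share one sire and one cage effect and differ only in their
residuals and thresholds — i.e. they are genetically perfectly correlated
in the generator, a deliberate simplification (the real traits are
distinct but strongly related measurements of the same damage process).

**Thresholds.** FS = 10/15/20 by cutting the liability at two points.
Only the reference trait means constrain the calibration (mean =
10 + 5[P(≥15) + P(=20)]), so the bald-patch fraction is a free generator
choice, taken to grow with the trait mean (0.04, 0.08, 0.18, 0.24 for
BACK45, NECK45, BACK70, NECK70). Cutpoints are expressed on the marginal
liability scale (fixed-effect variance included) so realized means hit
their targets (11.32 / 12.42 / 13.98 / 14.78) regardless of the
fixed-effect structure; drawn factor effects are centered exactly so no
dataset-level offset survives.

**Survival.** One liability per bird (variance 1, sire variance
`sigma2_S_surv` = 0.015, genetic correlation with FS 0.4 — the middle of
the plausible 0.2–0.6 range) with two cutpoints giving 98% survival to 45
weeks and 94% to 70 weeks; a bird dead at 45 weeks is dead at 70 weeks,
and dead birds have no FS at that age. Survival carries no fixed effects,
which keeps the realized rates exactly calibrated.

**Fixed effects.** An RT number identifies batch, farm and row; the two
rows of a batch share its farm and housing date, so the RT factor is
genuinely distinct from (not nested in) the farm x date x cross
interaction. Batch and interaction effects are N(0, 0.15²) each; the
fast-feathering gene is a sire-line genotype (frequency 0.3) shifting the
liability by 0.2. The interaction is encoded as a single combined factor
level per unique triple.

**Variance components.** Defaults (liability scale, non-fixed variance
normalized to 1): σ²_S = 0.026, σ²_c = 0.05, σ²_e = 0.924. These are
calibrated so that, after threshold attenuation on the observed score
scale, the cage-level sire-model expected accuracy
√[σ²_S/(σ²_S + σ²_e,cage/m)] sits near 0.62 at the design sizes — the
moderate-accuracy regime this testing scheme operates in. The cage
variance is kept small relative to the residual so the cage-mean noise
term dominates the non-sire variance, as in cage-mean data generally.

**Working datasets.** The raw data report per-cage score *counts*, not
individual scores. The individual-level working dataset therefore
re-allocates each cage's counts to random surviving members (dead members
get missing records, survival coded 2/1, monotone across ages); this is
exactly equivalent for genetic analysis because all cage members share
the same pedigree. The cage-level dataset holds the mean score of
survivors (missing when no survivors — such cages stay in the survival
data but are excluded from FS means), the survival fraction
n_alive/n_original, and the id of one random member used by the
cage-level animal model. A `continuous_cage_dataset` variant returns cage
means of the liability itself; it exactly satisfies the linear model
assumptions and is used wherever a check needs a correctly specified
model (BLUP dispersion, variance recovery).

## Relationship matrices

`build_A` uses the tabular method (dense, for desk-scale pedigrees and
oracles); `build_A_inverse` assembles Henderson's rules sparsely with
inbreeding from the Meuwissen–Luo recursion and also returns
log|A| = Σ log d_i, which the REML likelihood needs. Unknown parents are
unrelated non-inbred founders — the correct reading of this design, where
every commercial dam is unidentified. Pedigrees must list parents before
offspring (which also excludes cycles); matrices are 0-indexed
internally, 1-based in the coordinate-format text writer.

## REML and BLUP

All six models reduce to y = Xb + Z u_g (+ V u_c) + e with a genetic
block whose precision is `G0⁻¹ ⊗ A⁻¹` and an optional iid cage block.
For bivariate models the residual is 2×2 per bird/cage with missing FS
handled by pattern (dead birds keep their survival equation); for IBAM
the FS–survival residual covariance is fixed at 0, because every bird
with an FS record is a survivor with the same survival code, leaving that
covariance with essentially no information. Sire-level and cage-level
bivariate models estimate it freely. Cage-level records are unweighted by
cage size.

Estimation maximizes the restricted log-likelihood directly via

    -2 logL_R = log|C| + log|R| + log|G| + y'Py + (n - p) log 2π,

where C is the mixed-model coefficient matrix, factorized sparsely with a
minimum-degree ordering on C + C' (the MME are arrow-shaped: dense
fixed-effect rows bordering sparse pedigree blocks, for which the default
column ordering fills in badly). Cross-products are computed once per
fit, so one likelihood evaluation is one sparse factorization.

Parameterization is log-Cholesky per covariance block (PSD by
construction); variances are floored at 1e-8 of the phenotypic variance
rather than allowed negative, and estimates within two orders of
magnitude of the floor are flagged as boundary. Optimization is L-BFGS-B
with finite-difference gradients. Bivariate fits run in two stages —
variances first with covariances fixed at zero, then all parameters from
that start, with restarts until the likelihood stops improving — because
the FS–survival residual covariance creates a nearly flat likelihood
ridge on which a cold-started quasi-Newton search can drift to extreme
but statistically equivalent parameter sets. Finite-difference steps are
1e-5 (univariate) and 1e-4 (bivariate), balancing likelihood roundoff
(which grows with record count) against truncation error. Non-convergence
is flagged on the result, never raised.

Fixed effects use treatment coding (first level dropped); remaining
dependent columns (confounded levels) are removed by pivoted QR and
logged. Estimated sire effects are the sire solutions for sire models and
half the sire's EBV for animal models, so all models are compared on the
transmitting-ability scale.

## Cross-validation

Cages are randomly partitioned into k = 10 near-equal folds, identical
across models and traits at a given seed. Masking removes all phenotypes
of the masked cages for the model's traits; pedigree links remain. Proxy
phenotypes Ȳ_obs are the residuals of a fixed-effects-only OLS on the
complete cage-level data, computed once. Per fold the package reports the
correlation r(ŝ, Ȳ_obs) over masked cages, the dispersion slope of
Ȳ_obs on ŝ, T², and the family-specific expected accuracy; the final
accuracy is the fold-mean correlation divided by the fold-mean
r(s, Ȳ_obs), with n̄ taken as the realized mean number of scored birds
per cage. Masked cages without a defined proxy are excluded and counted;
folds with fewer than three usable cages are skipped.

The r(s, Ȳ_obs) correction needs individual-level variance components.
The default source is the individual bivariate animal model (IBAM); since
the correction is one shared scalar per fold, any individual-level model
gives an equivalent comparison, and the package also provides an
auxiliary individual-level univariate sire model (`IUSiM`, not one of the
six compared models) whose mixed-model equations are two orders of
magnitude smaller — the acceptance runs use it.

EMMEANs treat fold as a blocking factor on the model × fold grid:
marginal means with the two-way residual MS, Tukey studentized-range
pairwise p-values, and compact letter display. Comparisons against a
constant (dispersion vs 1) use each model's plain over-fold standard
error, since fold blocks do not cancel against a constant. Accuracy
EMMEANs are computed on raw correlations, not Fisher-z.

## What the tests do and do not show

Problem sizes were chosen to exercise the study design while keeping the
full suite and the acceptance script to a few minutes: equivalence and
cross-validation checks run at 200 sires (the CV accuracy estimator then
has Monte-Carlo spread of roughly ±0.05 around its level, which is why
the overall accuracy is averaged over the four FS traits); calibration
checks use ~50,000 birds; dispersion and variance-recovery checks use 20
replicates of 100–150 sires on continuous-liability records, where the
fitted model is exactly the generating model.

Passing tests show that the estimation machinery is correct (against
dense GLS, balanced ANOVA, dense-likelihood and recursive-kinship
oracles), that the generator is calibrated to the reference descriptive
statistics, and that the validation statistics behave as theory predicts
on data satisfying the design assumptions. They do not show how the
models rank on real recurrent-test records: the generator has no
trait-specific genetic structure across body regions or ages, no
dam-line structure, no behavioral dynamics within cages, and its FS
liability is exactly Gaussian. Known limitations: sire inbreeding makes
animal and sire models inequivalent to a small degree (the sire model
assumes a constant absorbed Mendelian variance); bivariate
individual-level fits sit on a flat residual-covariance ridge, so their
reported covariances are noisy even when fits are statistically
equivalent; and the liability-scale vs observed-scale distinction for
categorical traits is handled only through calibration, not by threshold
(probit) models, mirroring the linear-observed-scale analysis choice.
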