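# Methods

This note records the statistical model, the numerical choices, the design
decisions taken where several defensible options existed, and what the
synthetic-data generator does and does not emulate.

## Model

All evaluations are linear mixed models for one pre-adjusted trait:

    y = 1*mu + Z1 g + Z2 d + e,
    g ~ N(0, Kg sg2),  d ~ N(0, Kd sd2),  e ~ N(0, I se2).

The only fixed effect is the intercept, because site and design effects are
removed in a separate adjustment stage (below); this keeps the genetic
models identical across pedigree, genomic and single-step variants. The
additive covariance Kg is the pedigree numerator matrix A (ABLUP), the
VanRaden genomic matrix G (GBLUP) or the single-step blend H (ssGBLUP); the
dominance covariance Kd is the genomic dominance matrix D or its
single-step blend HD. Trees present in a covariance matrix but without
phenotypes (parents, cross-validation trees) receive predictions and
prediction error variances through the same equations.

Ratios reported: h2 = sg2/T, d2 = sd2/T, H2 = (sg2+sd2)/T with
T = sg2+sd2+se2. Standard errors of ratios use the first-order delta
method on the AI-matrix-based covariance of the variance components.

### Relationship matrices

* A: tabular method over the validated, topologically ordered pedigree;
  unknown parents are treated as unrelated non-inbred founders. Inbreeding
  is read off the diagonal (F = diag - 1).
* G and D: allele frequencies are the observed frequencies in the genotyped
  sample (no attempt at base-population frequencies; nothing in the data
  identifies them). Missing genotypes contribute zero to both codings,
  which is numerically identical to mean (2p) imputation.
* Scale matching: Ga = beta*G + alpha with (beta, alpha) solving the
  two-moment system Avg.diag(G)b+a = Avg.diag(A22),
  Avg.offdiag(G)b+a = Avg.offdiag(A22).
* H and HD: standard single-step block construction. The genotyped block
  uses Gw = (1-w) Ga + w A22 with default w = 0.05 to guarantee an
  invertible genotyped block; w is exposed everywhere it matters and w = 0
  gives the unweighted blend (H22 = Ga exactly). A ridge of 1e-8 on A22 is
  applied only if its Cholesky fails, and is recorded in the matrix
  metadata and the run log.
* Pedigree dominance matrix: the identity. With unrecorded sires, maternal
  half-sibs have pedigree dominance relationship zero, so OP pedigrees
  carry no non-trivial dominance structure; all dominance information
  enters through D.

### REML

Variance components maximize the restricted likelihood. Two routes:

* Single random term + residual: exact spectral profile. One
  eigendecomposition of the term's observation covariance reduces the
  profiled REML log-likelihood to a 1-D function of the variance ratio,
  maximized by bounded scalar optimization (log-ratio in [-30, 30],
  xatol 1e-10).
* Two terms (additive + dominance): average-information (AI) REML with a
  guaranteed-ascent line search. Each iteration computes the REML score
  and AI matrix; the AI step is step-halved (up to 12 times) until the
  restricted likelihood does not decrease, falling back to the monotone
  EM-REML update when the AI direction cannot ascend. Components whose AI
  update leaves the parameter space take the EM update; components pinned
  at the variance floor with an outward-pointing score are frozen there
  (active set), which avoids the notoriously slow EM crawl toward a zero
  variance component (relevant for traits with no dominance signal).

Starting values split var(y) equally across components. Convergence:
|change in logL| < 1e-8 and relative parameter change < 1e-6; variances are
floored at 1e-10 * var(y); maximum 200 iterations, after which a
ConvergenceError carrying the full trajectory is raised. The reported logL
omits additive constants (like most REML software); differences of logL
between models on the same data are unaffected.

AIC is reported as -2 logL + 2 — the convention of the mixed-model software
whose output this package mirrors, where the printed AIC equals
-2 logL + 2 regardless of the parameter count — with the conventional
-2 logL + 2k also available (`aic_conventional`).

### BLUP and PEV

Predictions use the projection form u_hat = s2 K Z' P y with
P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1, and prediction error variances
PEV = diag(s2 K - s2^2 K Z' P Z K); both are algebraically identical to
solving Henderson's mixed-model equations and reading the inverted
coefficient matrix (verified against an explicit MME oracle in the tests).
Theoretical accuracy is r_i = sqrt(1 - PEV_i/(sa2 (1+F_i))) with F_i from
the diagonal of the additive covariance; radicands below -1e-10 raise,
smaller negative roundoff is clipped to zero.

## Phenotype adjustment

Order: (1) conical volume from DBH and height, V = pi (DBH/2)^2 Ht / 3
(DBH and Ht in dm, V in dm^3); (2) per-site linear map of every
non-reference site to the reference site's sample mean and SD (ddof = 1) —
exactly what a MEAN/STD standardization procedure does; (3) per trait, a
random family-by-replicate (within site) effect is estimated by REML and
its BLUP subtracted, keeping the grand mean so adjusted phenotypes stay on
the trait scale. Volume is computed from raw measures and then standardized
as its own trait.

A consequence worth knowing: because family-by-replicate cells nest
families, subtracting their BLUPs absorbs part of the between-family
genetic signal, attenuating downstream heritability estimates by roughly
0.03-0.06 at the problem sizes used here. This is a property of the
adjustment design itself (shared with the field workflow this package
mirrors), not of the REML estimator — the parameter-recovery experiment
therefore evaluates the estimator on simulations without design effects,
and the pipeline-level numbers should be read as "post-adjustment" ratios.

## Cross-validation

Folds: random (10 folds, sizes differ by at most 1), balanced-family
(5 folds; each family's trees are shuffled and dealt round-robin from a
random offset, so every fold receives floor or ceil of n_f/5 trees of each
family), family (one fold per family with >= 8 trees; smaller families are
excluded from validation but remain in training). Fold assignment is
deterministic given (scheme, ids, seed).

Within each fold the validation trees' phenotypes are dropped and the model
is refit by REML on the training trees only (a config switch reuses the
full-data components instead); relationship matrices are unchanged, so
predictions for validation trees come from the same mixed-model equations.
Metrics are computed per fold and summarized as mean, SD and
SE = SD/sqrt(n_folds) — fold-averaged, not pooled, which matches the
mean (SE) reporting convention and avoids fold-size weighting ambiguity.
Predictive ability correlates CV predictions with adjusted phenotypes;
prediction accuracy correlates them with the full-data predictions of the
same type (EBV/MBV/GEBV or MGV). Pedigree-only models are skipped under
family folding, where their predictions collapse to the training family
mean.

## Synthetic data generator

The generator emulates the data-generating structure the analysis assumes:

* maternal OP families whose true sires are drawn per family from a small
  donor pool (`full_sib_concentration`, default 5 effective donors), with
  probability `selfing_rate` (default 0.05) of selfing — producing hidden
  full-sib clusters and occasional inbreds while the *recorded* pedigree
  lists every sire as unknown;
* unrelated founders, marker genotypes binomial(2, p) with p uniform on
  (0.05, 0.95), offspring by per-locus Mendelian gene dropping;
* traits built from a QTL subset of the genotyped markers: additive
  effects on the centered count coding and dominance effects on the
  heterozygosity coding, each component rescaled so its realized sample
  variance hits the target ratio exactly (defaults h2 = 0.35 with
  d2 = 0.45 / 0.42 for the growth traits and d2 = 0 for the
  wood-chemistry trait, mirroring the trait architectures of the field
  study the defaults emulate); the rescaling gives recovery tests a sharp
  truth — realized ratios are defined on component variances, and the
  residual cross-component sample covariances are left in place;
* two trial sites with different means and scales (one with 6 replicates,
  one with 30, echoing multi-tree-plot vs single-tree-plot layouts), plus
  normal family-by-replicate effects (SD 0.3 on the unit-variance core
  scale) and a site shift (SD 0.5); the wood trait is measured only on
  genotyped trees. Default sizes are the full study conditions (244
  families, ~24 progeny, 2,023 markers, 28 genotyped families).

Not emulated: linkage (markers drop independently, so LD exists only
through co-inheritance within pedigrees and the QTL-in-panel design),
selection across generations, spatial field trends, missing-phenotype
mechanisms other than the genotyped-only wood trait, and genotyping error.
Passing recovery tests therefore show that the estimators are correct under
the assumed model, not that real-data LD decay or selection histories are
handled.

## Problem sizes used in tests and the acceptance script

Simulations are run at reduced sizes chosen so the whole suite and the
acceptance script each finish comfortably on a single CPU while keeping
sampling error well inside the asserted tolerances:

* parameter recovery: 100 families x 15 progeny (n = 1500), 500 markers,
  200 QTL, 5 seeds (the recovery band of +-0.05 is several times the
  empirical seed-to-seed SD at this size);
* acceptance pipeline: 60 families x 20 progeny over two sites, 28
  genotyped families x 15 trees (~420 genotyped, close to the 423 of the
  motivating study), 600 markers;
* dominance pattern checks: 24 genotyped families x 14 trees, 2 effective
  donors per family (strong full-sib structure), d2 = 0.5, 10 seeds.

## Known limitations

* Dense algebra throughout: fits are O(n^3) per REML iteration (two-term
  models) or one O(n^3) eigendecomposition (single-term models); fine to a
  few thousand trees, not tuned for hundred-thousand-tree evaluations (no
  sparse A-inverse, no APY).
* Single-trait models only; no multi-trait REML, no epistasis, no
  genotype-by-environment interaction terms (the site standardization
  assumes rank-preserving site differences, consistent with the low GxE
  reported for these trials).
* The dominance centering of D is exact only under Hardy-Weinberg
  proportions; with strong inbreeding the dominance variance definition
  itself becomes parameterization-dependent.
* SEs of variance components and ratios are asymptotic (AI-matrix /
  delta-method); near a variance boundary they understate uncertainty.
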