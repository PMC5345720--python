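# Methods

## The model

`hatcv` works with the standard single-kinship mixed model of genomic
prediction,

    y = X beta + xi + e,
    xi ~ N(0, A sigma_xi^2),   e ~ N(0, I sigma^2),

where `y` are `n` phenotypes, `X` an `n x p` fixed-effect design,
`A` the `n x n` marker-inferred kinship matrix, `xi` the polygenic
effects, and `e` the residuals.  The variance ratio
`lambda = sigma^2 / sigma_xi^2` plays the role of a ridge/smoothing
parameter; the genomic heritability is `h2 = 1 / (1 + lambda)`.

Variance components are estimated by REML.  With the eigendecomposition
`A = U D U'`, rotating `(y, X)` by `U'` makes
`V = A sigma_xi^2 + I sigma^2` diagonal, `sigma_xi^2 (D + lambda I)`;
`beta` and `sigma_xi^2` then profile out analytically and a single
bracketed scalar search on `log lambda` (coarse 41-point grid on
`[1e-6, 1e6]`, then bounded Brent to 1e-8) maximizes the restricted
likelihood.  Only likelihood differences and the argmax are meaningful;
the additive constant is dropped.  If the optimum sits on a bracket
edge the fit carries an explicit boundary flag, and if the profile is
flat (range < 1e-6 across the bracket, e.g. `A = I`, where only
`sigma_xi^2 + sigma^2` is identifiable) the fit is flagged
non-identifiable and a warning is raised rather than reporting an
arbitrary ratio.

## Predictability without refitting

The whole-sample BLUP is a linear smoother of the centered phenotypes
`xi = y - X beta_hat`:

    xi_hat = H_R xi,
    H_R = sigma_xi^2 A V^-1 = U diag(d_j / (d_j + lambda)) U'.

The form `d_j / (d_j + lambda)` stays defined when eigenvalues are
exactly zero, which is routine for marker-inferred kinship.  For a
K-way partition of the sample, the estimated residuals
`e_hat_k = xi_k - xi_hat_k` of fold `k` are corrected by the fold's
diagonal block of `H_R`:

    e_k = (I - H_kk)^-1 e_hat_k,
    PRESS = sum_k e_k' e_k,
    R^2 = 1 - PRESS / SS,

with `SS` the total sum of squares of the centered phenotypes.  At
fixed `lambda` and fixed whole-sample `beta_hat` this correction is
*exact*: `e_k` equals the residual a BLUP refit without fold `k` would
produce.  The test suite verifies this against a brute-force
fold-deletion oracle at machine precision for K in {2, 5, 10, n}.  The
method is approximate only insofar as true cross-validation would
re-estimate `lambda` and `beta` per training fold; the package ships
the true CV engine so that the size of that approximation can always
be measured.  Leave-one-out is the `K = n` special case,
`e_j = e_hat_j / (1 - h_jj)`; GCV replaces each `h_jj` by the mean
leverage, `GRESS = sum e_hat_j^2 / (1 - h_bar)^2`, and coincides with
the LOO PRESS whenever all leverages are equal (e.g. `A = I`).

Leverages `h_jj` are "conflict-of-interest factors" — the contribution
of an observation to its own prediction.  A leverage within 1e-10 of 1
raises an error naming the observation (the `lambda -> 0` degenerate
case), rather than silently dividing by ~0.

For prediction of fixed effects only, the V^-1-weighted fixed-model hat
matrix `H_F = X (X' V^-1 X)^-1 X' V^-1` is available, as is the mixed
form `H_M = H_F + H_R (I - H_F)` that maps observed `y` to fitted
`X beta_hat + xi_hat` and corrects conditional residuals.

## Kinship

Genotypes at biallelic markers are coded -1/0/+1 (allele dosage minus
one).  The kinship is `A = (1/a) Z Z'` with `a = tr(Z Z') / n`, so
`trace(A) = n` by construction.  Flags allow per-marker centering and
standardization (monomorphic markers are dropped under standardization,
kept raw otherwise); the default is the raw cross-product.  Missing
calls are imputed with the per-marker mean of observed codes, which
preserves marker means and keeps `A` positive semidefinite.
Eigenvalues within `1e-8 * d_max` below zero are clipped to zero; the
shrinkage factors tolerate exact zeros but not negatives.

## True cross-validation

`kfold_cv` partitions the sample (seeded shuffle, round-robin labels,
fold sizes differing by at most one), re-estimates REML variance
components per training fold (warm-started near the whole-sample
estimate, which per-fold estimates rarely leave), re-estimates `beta`
by GLS, and predicts each test fold from the kinship blocks,

    xi_hat_k = sigma_xi^2 A[k,-k] (A[-k,-k] sigma_xi^2 + I sigma^2)^-1
               (y[-k] - X[-k] beta_hat).

The training kinship is the sub-block of the whole-sample `A`, not a
recomputation from training genotypes — the partition applies to the
single relationship matrix.  `SS` is computed from the concatenated
per-fold centered phenotypes of that partition (each fold centered by
its own training `beta_hat`), so it can vary slightly across
partitions when `beta` is re-estimated; with a fixed `beta` it is
partition-invariant.  `replicate_cv` averages R^2 over replicated
random partitions and reports the standard error (absent for a single
replicate; zero for leave-one-out, whose partition is unique).

## Tuning the variance ratio

`tune_lambda` treats `lambda` as a tuning parameter: phenotypes are
centered once with the whole-sample REML fit, then `R^2(lambda)` of the
LOO HAT (or GCV) criterion is maximized over a log grid spanning one
decade either side of the REML estimate, refined by bounded Brent.
The REML estimate is always evaluated, so the returned maximum
dominates `R^2(lambda_REML)` by construction.

Two design points deserve emphasis, both verified against brute-force
delete-one refits:

* Re-centering the phenotypes with a fresh GLS `beta_hat` at every
  trial `lambda` is wrong: as `lambda -> 0` the GLS weight on a
  kinship null direction diverges and strips exactly the phenotype
  component the leverage correction needs, inflating the apparent R^2.
  The phenotypes are therefore centered once.
* The search is local by design.  Far below the REML estimate the
  leverages saturate (`h_jj -> 1` once the kinship can interpolate the
  phenotypes, which any full-rank or `m > n` kinship can), and the
  corrected residuals shrink toward zero for *any* phenotype vector in
  the span of the nonzero eigendirections — `R^2(lambda)` then climbs
  spuriously toward 1 even though true held-out accuracy (which the CV
  engine measures) does not.  An optimum on the bracket edge should be
  inspected against the returned profile and against true CV before
  being trusted.

## Synthetic data

The generator emulates the generating model directly: marker allele
frequencies drawn uniformly from a MAF range (default 0.05–0.5),
genotypes as two independent Hardy–Weinberg alleles coded -1/0/+1, and
traits `y = X beta + xi + e` with variances scaled to a target
heritability.  The polygene is drawn either from the kinship
(`xi = U sqrt(D) z`, matching the model exactly) or from per-marker
effects on centered codes (exercising the full marker-to-kinship
pipeline); optional environment replicates share `xi` and redraw `e`,
feeding the balanced two-way ANOVA heritability estimator
(`sigma_E^2 = MS_E`, `sigma_G^2 = (MS_G - MS_E)/r`, clamped at zero).

The generating kinship is the *centered* one.  Without centering, the
raw cross-product kinship carries a large shared component (every
`Z_k` mean enters every entry; empirically `1'A1/n` is in the hundreds
at n=500, m=400) that inflates no individual difference yet would be
counted as polygenic variance, biasing the realized heritability of
the draws well below target.  With centering, `1'A1 = 0` exactly and
the realized variance ratio is unbiased (checked by a 200-replicate
Monte-Carlo test).

What the generator does *not* emulate: linkage disequilibrium,
population structure or family relatedness, dominance/epistasis, and
ascertainment.  Its individuals are essentially unrelated, so absolute
predictability on synthetic data is low (R^2 near zero at n of a few
hundred) even at substantial heritability — exactly as theory predicts
for unrelated samples.  Passing tests therefore demonstrate the
*internal* guarantees (exactness of the leverage correction, REML
calibration, HAT/CV/GCV agreement and ordering relative to FIT), not
the absolute R^2 levels reachable in structured populations such as
biparental inbred lines, where relatedness is strong and
predictability is high.

## Problem sizes and numerical choices

The default test and acceptance workloads use a frozen small dataset
(n=60, m=200, h2=0.5, seed 58), an inbred-study shape (n=210, m=1619)
for the method comparison, 200 replicates at n=500, m=1000 per
heritability level for REML calibration, and a scaled-down large-cohort
shape (n=1200, m=2500) for the end-to-end smoke run; these sizes keep a
full run in the low tens of seconds on one CPU while leaving every
quantity measurably away from its asymptotic regime.  Full `H_R`
materialization is refused above n=10,000 unless forced; diagonals and
fold blocks are always computed from `U` and the shrinkage factors.
FIT is reported both as the squared correlation of `(xi, xi_hat)` and
as `1 - ERESS/SS`; the two are close but not interchangeable, so both
are stored.  Negative R^2 is reported as-is — PRESS > SS means the
model predicts worse than the phenotype mean, which is worth seeing.

## Known limitations

* Single kinship only; multi-kernel covariance structures (dominance,
  epistasis, multiple relationship matrices) are out of scope.
* The HAT correction is exact only at fixed `lambda` and whole-sample
  `beta`; with per-fold re-estimation it is an approximation whose
  (small, slightly optimistic) bias the CV engine can quantify but the
  HAT method itself cannot.
* The ANOVA heritability estimator requires a balanced genotype x
  environment layout.
* Text formats and VCF only; no PLINK binary ingestion.
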