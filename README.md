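# hatcv

Fast, refit-free predictability for GBLUP genomic prediction.

Judging a genomic selection model requires an unbiased estimate of how
well it predicts individuals it has not seen — usually K-fold
cross-validation (CV), which refits the mixed model K times per
partition, times however many replicate partitions are needed to tame
partitioning noise.  For a mixed model with a marker-inferred kinship,
that cost is what makes leave-one-out CV "unrealistic" at scale and
multi-trait screens (hundreds of metabolites, say) a multi-day job.

`hatcv` computes the same quantity from a **single** whole-sample REML
fit.  The BLUP of the polygenic effects is a linear smoother of the
centered phenotypes, `xi_hat = H_R xi` with

    H_R = sigma_xi^2 A (A sigma_xi^2 + I sigma^2)^-1
        = U diag(d_j / (d_j + lambda)) U',      lambda = sigma^2 / sigma_xi^2,

where `A = U D U'` is the kinship eigendecomposition.  Dividing each
fold's estimated residuals by `(I - H_kk)` — the fold's leverage or
"conflict-of-interest" block — yields exactly the residuals that a
refit without that fold would have produced (at fixed `lambda` and
whole-sample `beta`).  From these predicted residuals:

    PRESS = sum_k e_k' e_k,        R^2 = 1 - PRESS / SS.

The package provides, behind one consistent interface:

* **kinship** — genotype coding (-1/0/+1, dosages, VCF), the normalized
  relationship matrix `A` (trace n), centering/standardization flags,
  and its eigendecomposition (paid once, reused for every trait and
  every `lambda`);
* **reml** — REML by eigen-rotation (the n-dimensional problem
  collapses to a 1-D search in `log lambda`), BLUE/BLUP, genomic
  heritability, FIT statistics, and a balanced two-way ANOVA
  heritability estimator for replicated trials;
* **hat** — fixed, random, and mixed hat matrices; leave-one-out and
  K-fold PRESS; GCV (GRESS); predictability; and local tuning of
  `lambda` for maximum predictability (MPE);
* **crossval** — the true cross-validation oracle with per-fold REML
  re-estimation and replicated random partitions, so the HAT
  approximation can always be checked against the real thing;
* **synthetic** — seed-deterministic generators for Hardy–Weinberg
  genotypes and polygenic traits with known heritability;
* a `hatcv` command-line tool wrapping all of the above with TSV/VCF
  input, TSV reports, and machine-readable run logs.

## Worked example

Simulate a small study (60 individuals, 200 markers, target
heritability 0.5), then compare the HAT leave-one-out predictability
with replicated true 10-fold CV:

```sh
hatcv simulate --n 60 --m 200 --h2 0.5 --seed 58 --outdir sim
hatcv predictability --geno sim/genotypes.tsv --pheno sim/phenotypes.tsv \
      --method hat --folds loo --center --outdir out
hatcv predictability --geno sim/genotypes.tsv --pheno sim/phenotypes.tsv \
      --method cv --folds 10 --reps 20 --seed 1 --center --outdir outcv
```

`out/predictability.tsv`:

```
trait  method  K   reps  lambda      h2          press        ss           r2             r2_mean       r2_se        fit_r2_corr   fit_r2_eress
y      HAT     60  1     1.38820922  0.4187237833  52.17679673  55.30228728  0.05651647871                             0.9209398208  0.6442358546
y      CV      10  20    1.38820922  0.4187237833  58.58306347  57.52668815  -0.0183632214  -0.05660584974  0.007396863133  0.9209398208  0.6442358546
```

Reading these numbers: REML estimates the variance ratio
`lambda = 1.388`, i.e. a genomic heritability of 0.42 (n=60 is a small
sample; the generating value was 0.5).  The model *fit* looks excellent
— squared correlation between centered phenotypes and BLUPs of 0.92,
ERESS-form FIT of 0.64 — but fit is not predictability: the HAT
leave-one-out R^2 is 0.057, and true 10-fold CV (mean of 20 random
partitions, with per-fold REML re-estimation) gives −0.057 ± 0.007.
Simulated individuals are unrelated, so near-zero predictability is the
correct answer here, the familiar gap between FIT and R^2 writ large;
the HAT value sits slightly above CV, its known mild optimism from
reusing the whole-sample `lambda` and `beta`.  On the same data the two
methods' PRESS values (52.2 vs 58.6) differ far less than either
differs from ERESS.

`hatcv tune` searches a decade either side of the REML `lambda` for the
maximum-predictability estimate; `hatcv fit` reports per-trait variance
components for multi-trait files while paying the eigendecomposition
once (the run log records the count).

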