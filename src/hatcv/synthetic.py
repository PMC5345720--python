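"""Synthetic genotypes and polygenic traits with known truth.

Genotypes are drawn marker by marker under Hardy-Weinberg equilibrium at
an allele frequency sampled uniformly from a MAF range, then coded
-1/0/+1.  Traits follow the GBLUP generating model
y = X beta + xi + e with xi ~ N(0, A sigma_xi^2) and e ~ N(0, I sigma^2),
the variances scaled so that sigma_xi^2 / (sigma_xi^2 + sigma^2) equals a
target heritability.  The polygene is drawn either directly from the
kinship (U sqrt(D) z, matching the model exactly) or from per-marker
effects (exercising the full marker-to-kinship pipeline).  Everything is
deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import GenotypeMatrix, KinshipEigen, compute_kinship


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    Defaults mirror a small inbred mapping population: modest sample
    size, a few hundred markers, intermediate heritability, and a single
    intercept as the fixed effect (units of y are arbitrary; h2 is the
    fraction of phenotypic variance that is polygenic).
    """

    n: int = 60
    m: int = 200
    h2: float = 0.5
    maf: tuple[float, float] = (0.05, 0.5)
    beta: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    n_env: int | None = None
    total_var: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        lo, hi = self.maf
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf range must be within (0, 0.5]")
        if self.n < 2 or self.m < 1:
            raise ValueError("need n >= 2 and m >= 1")


def simulate_genotypes(spec: SimulationSpec,
                       rng: np.random.Generator | None = None
                       ) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: two independent alleles per individual."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    p = rng.uniform(spec.maf[0], spec.maf[1], size=spec.m)
    alleles = rng.random((2, spec.n, spec.m)) < p[None, None, :]
    codes = alleles.sum(axis=0).astype(float) - 1.0  # dosage - 1
    ids = [f"ind{i + 1}" for i in range(spec.n)]
    mids = [f"m{k + 1}" for k in range(spec.m)]
    return GenotypeMatrix(ids, mids, codes)


def simulate_trait(kin, spec: SimulationSpec, X=None,
                   rng: np.random.Generator | None = None,
                   mode: str = "kinship"):
    """Draw a polygenic trait; returns (phenotypes, truth).

    Parameters
    ----------
    kin
        A :class:`KinshipEigen` (kinship mode) or a
        :class:`GenotypeMatrix` (either mode; required for marker mode).
    X
        Fixed-effect design, default a column of ones matching
        ``spec.beta`` of length 1.
    mode
        ``"kinship"`` draws xi = U sqrt(D) z directly from the polygenic
        covariance; ``"marker"`` draws per-marker effects
        b_k ~ N(0, sigma_xi^2 / a) on mean-centered codes, so that
        cov(Z b) = A sigma_xi^2 exactly for the centered kinship.

    Returns
    -------
    pheno : pandas.DataFrame with columns id, y (plus env replicates
        y_env1.. when ``spec.n_env`` is set; replicates share xi and
        redraw e)
    truth : dict with beta, xi, sigma_xi2, sigma2, h2
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    geno = None
    if isinstance(kin, GenotypeMatrix):
        geno = kin
        kin = compute_kinship(geno, center=True)
    if not isinstance(kin, KinshipEigen):
        raise TypeError("kin must be a KinshipEigen or GenotypeMatrix")
    n = kin.n

    sigma_xi2 = spec.total_var * spec.h2
    sigma2 = spec.total_var * (1.0 - spec.h2)
    if sigma2 == 0.0 and spec.h2 < 1.0:
        raise ValueError("zero residual variance requires h2 = 1")

    if X is None:
        X = np.ones((n, spec.beta.size))
        if spec.beta.size > 1:
            X[:, 1:] = rng.standard_normal((n, spec.beta.size - 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))

    if mode == "kinship":
        kin = kin.require_eigen()
        if kin.D.min() < -1e-8:
            raise ValueError("kinship not PSD")
        xi = kin.U @ (np.sqrt(np.clip(kin.D, 0, None) * sigma_xi2)
                      * rng.standard_normal(n))
    elif mode == "marker":
        if geno is None:
            raise ValueError("marker mode needs a GenotypeMatrix")
        # cov(Zc b) = Zc Zc' sigma_xi2 / a = A sigma_xi2 exactly
        Zc = geno.codes - geno.codes.mean(axis=0, keepdims=True)
        b = rng.standard_normal(geno.m) * np.sqrt(sigma_xi2 / kin.a)
        xi = Zc @ b
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ids = kin.individual_ids or [f"ind{i + 1}" for i in range(n)]
    mu = X @ spec.beta
    e = rng.standard_normal(n) * np.sqrt(sigma2)
    pheno = pd.DataFrame({"id": ids, "y": mu + xi + e})
    if spec.n_env is not None:
        if spec.n_env < 2:
            raise ValueError("n_env must be >= 2 when given")
        for r in range(spec.n_env):
            e_r = rng.standard_normal(n) * np.sqrt(sigma2)
            pheno[f"y_env{r + 1}"] = mu + xi + e_r
    truth = {"beta": spec.beta.copy(), "xi": xi, "sigma_xi2": sigma_xi2,
             "sigma2": sigma2, "h2": spec.h2, "X": X}
    return pheno, truth


def simulate_dataset(spec: SimulationSpec, mode: str = "kinship"):
    """Genotypes + kinship + trait in one deterministic call.

    Returns (geno, kin, pheno, truth); the single ``spec.seed`` drives
    both the genotype and trait draws.  The kinship used to generate
    (and returned) is the mean-centered one: without centering, A
    carries a large shared component (all Z_k means enter every entry)
    that inflates no individual difference yet would count as polygenic
    variance, biasing the realized heritability of the draws.
    """
    rng = np.random.default_rng(spec.seed)
    geno = simulate_genotypes(spec, rng)
    kin = compute_kinship(geno, center=True)
    if mode == "marker":
        pheno, truth = simulate_trait(geno, spec, rng=rng, mode="marker")
    else:
        pheno, truth = simulate_trait(kin, spec, rng=rng, mode="kinship")
    return geno, kin, pheno, truth
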