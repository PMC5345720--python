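"""REML fitting of the single-kinship mixed model by eigen-rotation.

Model: y = X beta + xi + e, with xi ~ N(0, A sigma_xi^2) and
e ~ N(0, I sigma^2), so var(y) = V = A sigma_xi^2 + I sigma^2.  Rotating
by the eigenvectors of A (A = U D U^T) turns V into the diagonal matrix
sigma_xi^2 (D + lambda I) with lambda = sigma^2 / sigma_xi^2.  Both beta
and sigma_xi^2 profile out analytically, leaving a one-dimensional
restricted likelihood in lambda that a bracketed scalar search maximizes.
The restricted log-likelihood is

    L = -1/2 [ ln|V| + ln|X^T V^-1 X| + (y - X beta)^T V^-1 (y - X beta) ],

up to an additive constant; only differences and the argmax are
meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .kinship import KinshipEigen

LOG_LAMBDA_BRACKET = (np.log(1e-6), np.log(1e6))
_FLAT_PROFILE_TOL = 1e-6


class RemlError(RuntimeError):
    """REML optimization failure; carries the evaluated lambda profile."""

    def __init__(self, msg: str, profile=None):
        super().__init__(msg)
        self.profile = profile


@dataclass
class MixedModelFit:
    """REML estimates, BLUE/BLUP, and goodness-of-fit statistics.

    ``xi_obs`` is the centered phenotype xi = y - X beta_hat ("observed"
    polygenic effect) and ``xi_hat`` its BLUP.  FIT is reported both as
    the squared correlation of (xi, xi_hat) and as 1 - ERESS/SS; the two
    are close but not identical.
    """

    beta_hat: np.ndarray
    sigma_xi2: float
    sigma2: float
    lambda_hat: float
    h2: float
    xi_hat: np.ndarray
    xi_obs: np.ndarray
    fit_r2_corr: float
    fit_r2_eress: float
    loglik: float
    lambda_identifiable: bool = True
    boundary: str | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def eress(self) -> float:
        return float(np.sum((self.xi_obs - self.xi_hat) ** 2))

    @property
    def ss(self) -> float:
        xi = self.xi_obs
        return float(np.sum((xi - xi.mean()) ** 2))


def _profile_loglik(log_lam: float, ys: np.ndarray, Xs: np.ndarray,
                    D: np.ndarray):
    """Restricted log-likelihood at lambda with beta, sigma_xi^2 profiled.

    Returns (loglik, beta_hat, sigma_xi2_hat) in the rotated basis.
    """
    lam = np.exp(log_lam)
    n, p = Xs.shape
    w = 1.0 / (D + lam)
    XtWX = (Xs * w[:, None]).T @ Xs
    XtWy = (Xs * w[:, None]).T @ ys
    try:
        c = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    beta = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ beta
    rss = float(r @ (w * r))
    if rss <= 0:
        return -np.inf, None, None
    sigma_xi2 = rss / (n - p)
    logdet_V = float(np.sum(np.log(D + lam)))
    logdet_XtWX = 2.0 * float(np.sum(np.log(np.diag(c))))
    ll = -0.5 * ((n - p) * np.log(sigma_xi2) + logdet_V
                 + logdet_XtWX + (n - p))
    return ll, beta, sigma_xi2


def reml_fit(y, X, eig: KinshipEigen, lambda_fixed: float | None = None,
             log_lambda_bracket=LOG_LAMBDA_BRACKET,
             xtol: float = 1e-8) -> MixedModelFit:
    """Fit the mixed model by REML (or profile at a user-fixed lambda).

    Parameters
    ----------
    y : (n,) phenotypes
    X : (n, p) fixed-effect design, full column rank, p < n
    eig : kinship with eigendecomposition (computed on demand)
    lambda_fixed : skip the variance-ratio search and profile at this value
    log_lambda_bracket : search interval on log(lambda)
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    n, p = X.shape
    if p >= n:
        raise ValueError("need more observations than fixed effects")
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotypes")
    if np.linalg.matrix_rank(X) < p:
        raise RemlError("fixed-effect design X is rank deficient")

    eig = eig.require_eigen()
    U, D = eig.U, eig.D
    ys, Xs = U.T @ y, U.T @ X

    warns: list[str] = []
    boundary = None
    identifiable = True
    lo, hi = log_lambda_bracket

    if lambda_fixed is not None:
        if lambda_fixed <= 0:
            raise ValueError("lambda_fixed must be positive")
        log_lam = np.log(lambda_fixed)
        ll, _, _ = _profile_loglik(log_lam, ys, Xs, D)
    else:
        grid = np.linspace(lo, hi, 41)
        vals = np.array([_profile_loglik(g, ys, Xs, D)[0] for g in grid])
        if not np.isfinite(vals).any():
            raise RemlError("restricted likelihood not finite anywhere on "
                            "the lambda bracket",
                            profile=list(zip(np.exp(grid), vals)))
        finite = vals[np.isfinite(vals)]
        if finite.max() - finite.min() < _FLAT_PROFILE_TOL:
            # e.g. A = I: V = (sigma_xi^2 + sigma^2) I and only the total
            # variance is identifiable.
            identifiable = False
            warns.append("restricted likelihood is flat in lambda; the "
                         "variance ratio is not identifiable (A close to "
                         "identity?)")
            warnings.warn(warns[-1], stacklevel=2)
        i = int(np.nanargmax(np.where(np.isfinite(vals), vals, -np.inf)))
        blo = grid[max(i - 1, 0)]
        bhi = grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda g: -_profile_loglik(g, ys, Xs, D)[0],
            bounds=(blo, bhi), method="bounded",
            options={"xatol": xtol})
        if not res.success:
            raise RemlError(f"lambda search failed: {res.message}",
                            profile=list(zip(np.exp(grid), vals)))
        log_lam = float(res.x)
        ll = -float(res.fun)
        if log_lam - lo < 1e-3:
            boundary = "sigma2_to_zero"      # lambda -> 0
        elif hi - log_lam < 1e-3:
            boundary = "sigma_xi2_to_zero"   # lambda -> inf
        if boundary:
            warns.append(f"optimum at bracket edge ({boundary})")

    ll, beta_s, sigma_xi2 = _profile_loglik(log_lam, ys, Xs, D)
    if beta_s is None:
        raise RemlError("restricted likelihood degenerate at the chosen "
                        "lambda")
    lam = float(np.exp(log_lam))
    sigma2 = lam * sigma_xi2
    h2 = 1.0 / (1.0 + lam)

    beta, xi_hat = blue_blup(y, X, eig, lam)
    xi_obs = y - X @ beta
    eress = float(np.sum((xi_obs - xi_hat) ** 2))
    ss = float(np.sum((xi_obs - xi_obs.mean()) ** 2))
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(xi_obs, xi_hat)[0, 1]
    fit_corr = float(c ** 2) if np.isfinite(c) else 0.0

    return MixedModelFit(
        beta_hat=beta, sigma_xi2=sigma_xi2, sigma2=sigma2, lambda_hat=lam,
        h2=h2, xi_hat=xi_hat, xi_obs=xi_obs, fit_r2_corr=fit_corr,
        fit_r2_eress=1.0 - eress / ss if ss > 0 else np.nan, loglik=ll,
        lambda_identifiable=identifiable, boundary=boundary, warnings=warns)


def blue_blup(y, X, eig: KinshipEigen, lam: float):
    """BLUE of beta and BLUP of xi at a given variance ratio lambda.

    beta_hat = (X^T V^-1 X)^-1 X^T V^-1 y and
    xi_hat = sigma_xi^2 A V^-1 (y - X beta_hat), evaluated in the rotated
    basis where V^-1 is diagonal (no n x n inverse is formed).  Both
    depend on the variance components only through lambda.
    """
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError("lambda must be positive and finite")
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eig = eig.require_eigen()
    U, D = eig.U, eig.D
    ys, Xs = U.T @ y, U.T @ X
    w = 1.0 / (D + lam)
    XtWX = (Xs * w[:, None]).T @ Xs
    XtWy = (Xs * w[:, None]).T @ ys
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError as exc:
        raise RemlError("singular X^T V^-1 X") from exc
    # sigma_xi2 A V^-1 = U diag(d/(d+lam)) U^T
    shrink = D / (D + lam)
    xi_obs_s = ys - Xs @ beta
    xi_hat = U @ (shrink * xi_obs_s)
    return beta, xi_hat


def anova_heritability(pheno: pd.DataFrame, genotype: str = "genotype",
                       env: str = "env", value: str = "value"):
    """Broad-sense heritability from a balanced genotype x environment trial.

    One observation per (genotype, environment) cell; the residual
    (genotype x environment) mean square estimates sigma_E^2 and the
    genotype mean square has expectation sigma_E^2 + r sigma_G^2, where r
    is the number of environments.  Returns (sigma_G2, sigma_E2, H2) with
    sigma_G2 clamped at zero when MS_G < MS_E.
    """
    df = pheno[[genotype, env, value]].dropna()
    wide = df.pivot_table(index=genotype, columns=env, values=value,
                          aggfunc="count")
    if wide.isna().any().any() or (wide != 1).any().any():
        raise ValueError("unbalanced layout: need exactly one observation "
                         "per genotype x environment cell")
    r = wide.shape[1]
    g = wide.shape[0]
    if r < 2:
        raise ValueError("need at least two environments")
    Y = pheno.pivot_table(index=genotype, columns=env,
                          values=value).to_numpy()
    grand = Y.mean()
    gm = Y.mean(axis=1)
    em = Y.mean(axis=0)
    ss_g = r * float(np.sum((gm - grand) ** 2))
    ss_e_env = g * float(np.sum((em - grand) ** 2))
    ss_t = float(np.sum((Y - grand) ** 2))
    ss_res = ss_t - ss_g - ss_e_env
    ms_g = ss_g / (g - 1)
    ms_e = ss_res / ((g - 1) * (r - 1))
    sigma_e2 = ms_e
    sigma_g2 = max((ms_g - ms_e) / r, 0.0)
    h2 = sigma_g2 / (sigma_g2 + sigma_e2) if sigma_g2 + sigma_e2 > 0 else 0.0
    return sigma_g2, sigma_e2, h2
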