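"""Hat matrices, leverage-corrected predicted residuals, PRESS/GRESS,
predictability, and variance-ratio tuning.

The whole-sample BLUP is a linear smoother of the centered phenotypes:
xi_hat = H_R xi with H_R = sigma_xi^2 A V^-1 = U diag(d_j/(d_j+lambda)) U^T.
The diagonal block H_kk of a hat matrix measures how much a fold's own
observations contributed to their own prediction ("conflict-of-interest
factor"); dividing the estimated residuals by (I - H_kk) recovers exactly
the residuals a refit without that fold would have produced, at fixed
lambda and whole-sample beta.  PRESS is the sum of squares of these
predicted residuals and predictability is R^2 = 1 - PRESS/SS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .crossval import FoldAssignment
from .kinship import KinshipEigen
from .reml import blue_blup, reml_fit

LEVERAGE_SATURATION = 1.0 - 1e-10
FULL_MATRIX_LIMIT = 10_000


@dataclass
class HatRandom:
    """Random-model hat matrix H_R = U diag(d_j/(d_j+lambda)) U^T.

    Stored in factored form; the diagonal and arbitrary diagonal blocks
    are computed from U and the shrinkage factors without materializing
    the n x n matrix.
    """

    lam: float
    U: np.ndarray
    shrink: np.ndarray

    @property
    def n(self) -> int:
        return self.U.shape[0]

    def diagonal(self) -> np.ndarray:
        return np.einsum("jt,t,jt->j", self.U, self.shrink, self.U)

    def block(self, idx: np.ndarray) -> np.ndarray:
        Uk = self.U[np.atleast_1d(idx), :]
        return (Uk * self.shrink[None, :]) @ Uk.T

    def full(self, force: bool = False) -> np.ndarray:
        if self.n > FULL_MATRIX_LIMIT and not force:
            raise ValueError(f"refusing to materialize a {self.n} x "
                             f"{self.n} hat matrix (pass force=True)")
        return (self.U * self.shrink[None, :]) @ self.U.T

    def apply(self, v: np.ndarray) -> np.ndarray:
        """H_R @ v without forming H_R."""
        return self.U @ (self.shrink * (self.U.T @ v))

    def trace(self) -> float:
        """Effective degrees of freedom sum_j d_j/(d_j+lambda)."""
        return float(self.shrink.sum())


@dataclass
class PredictabilityResult:
    """PRESS (or GRESS), total SS, and predictability R^2 = 1 - PRESS/SS.

    ``r2`` is never clamped: a negative value means the model predicts
    worse than the phenotype mean.  ``residuals_pred`` is None for GCV
    (which corrects only the sum of squares, not individual residuals).
    """

    method: str
    folds: int | None
    press: float
    ss: float
    r2: float
    residuals_pred: np.ndarray | None = None
    lambda_used: float | None = None
    rep_mean: float | None = None
    rep_se: float | None = None
    per_rep: list[float] = field(default_factory=list)


def hat_fixed(X, W=None) -> np.ndarray:
    """Fixed-model hat matrix H_F = X (X^T W X)^-1 X^T W (idempotent, rank p).

    With W = V^-1 this is the GLS projector used for marginal prediction
    under the mixed model; with W = I it is the ordinary least-squares
    hat matrix.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if W is None:
        WX = X
    else:
        W = np.asarray(W, dtype=float)
        WX = W @ X
    XtWX = X.T @ WX
    try:
        core = np.linalg.solve(XtWX, WX.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular X^T W X") from exc
    return X @ core


def hat_random(eig: KinshipEigen, lam: float) -> HatRandom:
    """Random-model hat matrix at variance ratio lambda > 0.

    The shrinkage factors d_j/(d_j+lambda) stay well defined when
    eigenvalues are exactly zero, which is routine for marker-inferred
    kinship (rank <= m).
    """
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError("lambda must be positive and finite (lambda = 0 "
                         "gives unit leverage and undefined LOO residuals)")
    eig = eig.require_eigen()
    shrink = eig.D / (eig.D + lam)
    return HatRandom(lam=float(lam), U=eig.U, shrink=shrink)


def hat_mixed(H_F: np.ndarray, H_R) -> np.ndarray:
    """Mixed hat matrix H_M = H_F + H_R (I - H_F).

    Maps observed y to fitted values X beta_hat + xi_hat when H_F is the
    V^-1-weighted fixed projector and H_R the random-model hat matrix.
    """
    H_F = np.asarray(H_F, dtype=float)
    R = H_R.full() if isinstance(H_R, HatRandom) else np.asarray(H_R)
    if H_F.shape != R.shape:
        raise ValueError("hat matrices have mismatched shapes")
    return H_F + R @ (np.eye(H_F.shape[0]) - H_F)


def _total_ss(xi: np.ndarray) -> float:
    return float(np.sum((xi - xi.mean()) ** 2))


def press_loo(residuals_est, leverages, ss: float | None = None,
              xi=None, lam: float | None = None) -> PredictabilityResult:
    """Leave-one-out PRESS from whole-sample residuals and leverages.

    e_j = e_hat_j / (1 - h_jj);  PRESS = sum e_j^2;  R^2 = 1 - PRESS/SS.
    """
    e_hat = np.asarray(residuals_est, dtype=float).ravel()
    h = np.asarray(leverages, dtype=float).ravel()
    sat = h >= LEVERAGE_SATURATION
    if sat.any():
        j = int(np.argmax(sat))
        raise ValueError(f"conflict-of-interest factor saturated at "
                         f"observation {j} (h_jj = {h[j]:.12g})")
    e = e_hat / (1.0 - h)
    press = float(e @ e)
    if ss is None:
        if xi is None:
            raise ValueError("provide ss or the centered phenotypes xi")
        ss = _total_ss(np.asarray(xi, dtype=float))
    return PredictabilityResult(method="HAT", folds=e.size, press=press,
                                ss=ss, r2=1.0 - press / ss,
                                residuals_pred=e, lambda_used=lam)


def press_kfold(residuals_est, hat, folds: FoldAssignment, W=None,
                ss: float | None = None, xi=None,
                lam: float | None = None) -> PredictabilityResult:
    """K-fold PRESS: per fold e_k = (I - H_kk)^-1 e_hat_k.

    ``hat`` is a :class:`HatRandom` (random model) or a full hat matrix
    (e.g. from :func:`hat_fixed`).  With a weight matrix W the PRESS is
    the weighted sum sum_k e_k^T W_k e_k, matching the weighted
    least-squares form of the fixed-model method.
    """
    e_hat = np.asarray(residuals_est, dtype=float).ravel()
    n = e_hat.size
    if folds.n != n:
        raise ValueError("fold assignment size mismatch")
    e_pred = np.empty(n)
    press = 0.0
    for k, idx in enumerate(folds.fold_indices()):
        Hkk = hat.block(idx) if isinstance(hat, HatRandom) \
            else np.asarray(hat)[np.ix_(idx, idx)]
        M = np.eye(idx.size) - Hkk
        try:
            ek = np.linalg.solve(M, e_hat[idx])
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"(I - H_kk) singular for fold {k + 1}") from exc
        e_pred[idx] = ek
        if W is None:
            press += float(ek @ ek)
        else:
            Wk = np.asarray(W)[np.ix_(idx, idx)]
            press += float(ek @ (Wk @ ek))
    if ss is None:
        if xi is None:
            raise ValueError("provide ss or the centered phenotypes xi")
        ss = _total_ss(np.asarray(xi, dtype=float))
    return PredictabilityResult(method="HAT", folds=folds.K, press=press,
                                ss=ss, r2=1.0 - press / ss,
                                residuals_pred=e_pred, lambda_used=lam)


def gcv_gress(residuals_est, hat: HatRandom, ss: float | None = None,
              xi=None) -> PredictabilityResult:
    """Generalized cross-validation: GRESS = sum e_hat_j^2 / (1 - h_bar)^2.

    h_bar is the mean leverage, so GRESS equals the LOO PRESS whenever
    all leverages coincide (e.g. A = I).
    """
    e_hat = np.asarray(residuals_est, dtype=float).ravel()
    h_bar = float(hat.diagonal().mean()) if isinstance(hat, HatRandom) \
        else float(np.asarray(hat, dtype=float).ravel().mean())
    if h_bar >= LEVERAGE_SATURATION:
        raise ValueError("mean leverage saturated (h_bar >= 1)")
    gress = float(e_hat @ e_hat) / (1.0 - h_bar) ** 2
    if ss is None:
        if xi is None:
            raise ValueError("provide ss or the centered phenotypes xi")
        ss = _total_ss(np.asarray(xi, dtype=float))
    lam = hat.lam if isinstance(hat, HatRandom) else None
    return PredictabilityResult(method="GCV", folds=None, press=gress,
                                ss=ss, r2=1.0 - gress / ss,
                                lambda_used=lam)


def predictability_at_lambda(xi, eig: KinshipEigen, lam: float,
                             objective: str = "hat_loo") -> float:
    """R^2 of the HAT-LOO or GCV method at variance ratio lam.

    ``xi`` is the phenotype vector centered once by the whole-sample
    fixed-effect estimate; only the random hat matrix varies with lam.
    (Re-centering per trial lam is deliberately avoided: as lam -> 0 the
    GLS weight on a kinship null direction diverges and strips exactly
    the phenotype component the leverage correction needs, inflating the
    apparent R^2 toward 1.)
    """
    xi = np.asarray(xi, dtype=float).ravel()
    hr = hat_random(eig, lam)
    e_hat = xi - hr.apply(xi)
    if objective == "hat_loo":
        return press_loo(e_hat, hr.diagonal(), xi=xi, lam=lam).r2
    if objective == "gcv":
        return gcv_gress(e_hat, hr, xi=xi).r2
    raise ValueError(f"unknown objective {objective!r}")


def tune_lambda(y, X, eig: KinshipEigen, objective: str = "hat_loo",
                fit=None, span_decades: float = 1.0,
                grid_points: int = 61):
    """Maximum-predictability estimate (MPE) of the variance ratio.

    Centers the phenotypes once with the whole-sample REML fit, then
    treats lambda as a tuning parameter of the random hat matrix alone:
    a log grid spanning ``span_decades`` decades around the REML
    estimate is scanned and the best bracket refined with bounded Brent.
    The REML estimate itself is always evaluated, so the returned
    maximum dominates r2(lambda_REML).

    The search is deliberately local (default one decade each way).
    Far below the REML estimate the leverages saturate (h_jj -> 1 for a
    full-rank or column-space-interpolating kinship) and the corrected
    residuals shrink toward zero for any phenotype in the span of the
    nonzero eigendirections; r2(lambda) then climbs spuriously toward 1
    even though true held-out prediction accuracy does not.  Widening
    the bracket invites that artifact; inspect the returned profile and
    the leverage diagnostics before trusting an edge optimum.

    Returns (lambda_mpe, r2_max, profile) where profile is the list of
    (lambda, r2) pairs evaluated on the grid.
    """
    if fit is None:
        fit = reml_fit(y, X, eig)
    lambda_reml = fit.lambda_hat
    xi = fit.xi_obs
    center = np.log10(lambda_reml)
    grid = np.concatenate([
        10.0 ** np.linspace(center - span_decades, center + span_decades,
                            grid_points),
        [lambda_reml],
    ])
    grid = np.unique(grid)
    r2s = np.array([predictability_at_lambda(xi, eig, g, objective)
                    for g in grid])
    if not np.isfinite(r2s).all():
        raise ValueError("non-finite predictability on the tuning grid")
    profile = list(zip(grid.tolist(), r2s.tolist()))
    i = int(np.argmax(r2s))
    lo = np.log(grid[max(i - 1, 0)])
    hi = np.log(grid[min(i + 1, grid.size - 1)])
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda g: -predictability_at_lambda(xi, eig, np.exp(g),
                                                objective),
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
        lam_best, r2_best = float(np.exp(res.x)), -float(res.fun)
    else:
        lam_best, r2_best = float(grid[i]), float(r2s[i])
    if r2s[i] > r2_best:  # refinement can never be allowed to lose
        lam_best, r2_best = float(grid[i]), float(r2s[i])
    return lam_best, r2_best, profile
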