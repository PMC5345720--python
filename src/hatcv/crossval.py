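"""True K-fold cross-validation for GBLUP, the oracle the HAT method
approximates.

Each fold is predicted from the remaining folds: variance components are
re-estimated by REML on the training sub-sample (or held fixed), fixed
effects are re-estimated by GLS, and the test fold's polygenic effect is
predicted from the kinship between test and training individuals,

    xi_hat_k = sigma_xi^2 A[k,-k] (A[-k,-k] sigma_xi^2 + I sigma^2)^-1
               (y[-k] - X[-k] beta_hat_{-k}).

PRESS accumulates (xi_k - xi_hat_k)^T (xi_k - xi_hat_k) over folds and
R^2 = 1 - PRESS/SS with SS the total sum of squares of the centered
phenotypes.  With re-estimation off, lambda fixed at the whole-sample
estimate and the whole-sample beta substituted, this reproduces the HAT
K-fold result to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .kinship import KinshipEigen, eigendecompose


@dataclass
class FoldAssignment:
    """Seed-reproducible balanced partition of 1..n into K folds."""

    n: int
    K: int
    assignment: np.ndarray  # fold label in 0..K-1 per individual
    seed: int | None = None

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.size != self.n:
            raise ValueError("assignment length mismatch")
        counts = np.bincount(self.assignment, minlength=self.K)
        if counts.size > self.K or counts.min() == 0:
            raise ValueError("assignment labels must cover 0..K-1")
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most one")

    def fold_indices(self):
        for k in range(self.K):
            yield np.flatnonzero(self.assignment == k)


def make_folds(n: int, K: int, seed: int | None = None) -> FoldAssignment:
    """Uniformly random balanced partition: seeded shuffle, round-robin
    labels."""
    if not 2 <= K <= n:
        raise ValueError(f"K must satisfy 2 <= K <= n (got K={K}, n={n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    labels[perm] = np.arange(n) % K
    return FoldAssignment(n=n, K=K, assignment=labels, seed=seed)


class CrossValError(RuntimeError):
    """A fold failed; carries the partial per-fold report."""

    def __init__(self, msg: str, partial=None):
        super().__init__(msg)
        self.partial = partial


def kfold_cv(y, X, kin: KinshipEigen, folds: FoldAssignment,
             reestimate: bool = True, lambda_fixed: float | None = None,
             beta_fixed=None, warm_start: float | None = None):
    """True cross-validation over a fold assignment.

    Parameters
    ----------
    reestimate
        Re-fit REML per training fold (warm-started at the whole-sample
        lambda).  With ``reestimate=False`` a ``lambda_fixed`` must be
        given and is used in every fold.
    beta_fixed
        Use this beta for centering instead of the per-fold GLS estimate
        (exactness tests against the HAT method fix both lambda and beta).

    Returns a :class:`hatcv.hat.PredictabilityResult` (method "CV") whose
    ``residuals_pred`` are the per-observation predicted residuals
    xi_k - xi_hat_k.
    """
    from .hat import PredictabilityResult  # deferred: hat imports folds
    from .reml import reml_fit

    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    A = kin.A
    if A.shape[0] != n:
        raise ValueError("kinship size does not match phenotypes")
    if not reestimate and lambda_fixed is None:
        raise ValueError("lambda_fixed is required when reestimate=False")

    xi_all = np.empty(n)
    resid = np.empty(n)
    lambdas = []
    per_fold = []
    for k, idx in enumerate(folds.fold_indices()):
        train = np.setdiff1d(np.arange(n), idx, assume_unique=True)
        if reestimate:
            sub = KinshipEigen(A=A[np.ix_(train, train)], a=kin.a)
            # warm start: per-fold lambda varies little around the
            # whole-sample estimate, so a narrowed bracket saves grid work
            if warm_start is not None and warm_start > 0:
                c = np.log(warm_start)
                bracket = (max(c - np.log(1e3), np.log(1e-6)),
                           min(c + np.log(1e3), np.log(1e6)))
            else:
                bracket = (np.log(1e-6), np.log(1e6))
            try:
                eigendecompose(sub)
                fit = reml_fit(y[train], X[train], sub,
                               log_lambda_bracket=bracket)
            except Exception as exc:
                raise CrossValError(
                    f"REML failed in fold {k + 1}: {exc}",
                    partial=per_fold) from exc
            lam = fit.lambda_hat
        else:
            lam = float(lambda_fixed)
        lambdas.append(lam)

        A_tt = A[np.ix_(train, train)]
        V_tt = A_tt + lam * np.eye(train.size)  # scaled by sigma_xi^2
        cho = linalg.cho_factor(V_tt, lower=True)
        if beta_fixed is not None:
            beta = np.asarray(beta_fixed, dtype=float).ravel()
        else:
            Vi_X = linalg.cho_solve(cho, X[train])
            Vi_y = linalg.cho_solve(cho, y[train])
            beta = np.linalg.solve(X[train].T @ Vi_X, X[train].T @ Vi_y)
        resid_train = y[train] - X[train] @ beta
        xi_k = y[idx] - X[idx] @ beta
        xi_hat_k = A[np.ix_(idx, train)] @ linalg.cho_solve(cho, resid_train)
        xi_all[idx] = xi_k
        resid[idx] = xi_k - xi_hat_k
        per_fold.append({"fold": k + 1, "lambda": lam,
                         "press": float(np.sum((xi_k - xi_hat_k) ** 2))})

    press = float(resid @ resid)
    ss = float(np.sum((xi_all - xi_all.mean()) ** 2))
    return PredictabilityResult(
        method="CV", folds=folds.K, press=press, ss=ss,
        r2=1.0 - press / ss, residuals_pred=resid,
        lambda_used=float(np.mean(lambdas)))


def replicate_cv(y, X, kin: KinshipEigen, K: int, reps: int,
                 seed: int | None = None, method: str = "cv",
                 lambda_fixed: float | None = None):
    """Mean and standard error of R^2 over replicated random partitions.

    ``method`` is "cv" (true cross-validation with per-fold REML) or
    "hat" (K-fold HAT at a fixed lambda, requiring ``lambda_fixed`` or a
    whole-sample REML fit computed here).  The returned result carries
    the per-replicate R^2 values; the SE is None for a single replicate.
    """
    from .hat import hat_random, press_kfold
    from .reml import blue_blup, reml_fit

    if reps < 1:
        raise ValueError("reps must be >= 1")
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)

    if method == "hat":
        kin = kin.require_eigen()
        if lambda_fixed is None:
            lambda_fixed = reml_fit(y, X, kin).lambda_hat
        beta, xi_hat = blue_blup(y, X, kin, lambda_fixed)
        xi = y - X @ beta
        e_hat = xi - xi_hat
        hr = hat_random(kin, lambda_fixed)

    r2s = []
    last = None
    for _ in range(reps):
        folds = make_folds(y.size, K, seed=int(rng.integers(2 ** 31)))
        if method == "hat":
            last = press_kfold(e_hat, hr, folds, xi=xi, lam=lambda_fixed)
        elif method == "cv":
            last = kfold_cv(y, X, kin, folds,
                            reestimate=lambda_fixed is None,
                            lambda_fixed=lambda_fixed)
        else:
            raise ValueError(f"unknown method {method!r}")
        r2s.append(last.r2)
    last.per_rep = r2s
    last.rep_mean = float(np.mean(r2s))
    last.rep_se = float(np.std(r2s, ddof=1) / np.sqrt(reps)) if reps > 1 \
        else None
    return last
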