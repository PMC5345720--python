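"""Marker-inferred kinship: genotype coding, the normalized relationship
matrix A, and its eigendecomposition.

Genotypes at a biallelic marker are coded -1 (A1A1), 0 (A1A2), +1 (A2A2);
an allele dosage d in {0, 1, 2} maps to d - 1.  The kinship matrix is

    A = (1/a) * Z Z^T,   a = tr(Z Z^T) / n,

so that trace(A) = n by construction.  The eigendecomposition A = U D U^T
is the workhorse of every downstream computation: it diagonalizes the
mixed-model covariance V = A*sigma_xi^2 + I*sigma^2 and makes the random
hat matrix H_R = U diag(d_j/(d_j+lambda)) U^T trivial to evaluate for any
variance ratio lambda.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: incremented by :func:`eigendecompose`; lets callers verify that an
#: expensive decomposition is paid only once per kinship matrix.
EIGEN_COUNT = 0

_GT_CODES = {
    "A1A1": -1.0, "A1A2": 0.0, "A2A1": 0.0, "A2A2": 1.0,
    "0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0,
    "0|0": 0.0, "0|1": 1.0, "1|0": 1.0, "1|1": 2.0,
}
_GT_MISSING = {"./.", ".|.", ".", "NA", "", "nan"}


@dataclass
class GenotypeMatrix:
    """n x m coded marker matrix with identifiers.

    ``codes`` holds values in {-1, 0, +1}; imputed cells hold the
    per-marker mean of the observed codes (hence lie in [-1, +1]).
    """

    individual_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        n, m = self.codes.shape
        if n < 2:
            raise ValueError("need at least two individuals")
        if m < 1:
            raise ValueError("need at least one marker")
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id lists do not match the code matrix shape")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if not np.isfinite(self.codes).all():
            raise ValueError("non-finite genotype codes")
        if self.codes.min() < -1 - 1e-9 or self.codes.max() > 1 + 1e-9:
            raise ValueError("genotype codes must lie in [-1, +1]")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]


@dataclass
class KinshipEigen:
    """Kinship matrix A (trace n after normalization) with eigen-pairs.

    ``U`` and ``D`` are filled by :func:`eigendecompose`; ``D`` is sorted
    descending and tiny negative eigenvalues are clipped to zero.
    """

    A: np.ndarray
    a: float
    individual_ids: list[str] | None = None
    U: np.ndarray | None = None
    D: np.ndarray | None = None
    dropped_markers: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def require_eigen(self) -> "KinshipEigen":
        if self.U is None or self.D is None:
            return eigendecompose(self)
        return self

    def subset(self, idx: np.ndarray) -> "KinshipEigen":
        """Sub-block of A for the given individuals (eigen part dropped)."""
        ids = None
        if self.individual_ids is not None:
            ids = [self.individual_ids[i] for i in np.atleast_1d(idx)]
        return KinshipEigen(A=self.A[np.ix_(idx, idx)], a=self.a,
                            individual_ids=ids)


def code_genotypes(calls, individual_ids=None, marker_ids=None,
                   missing_policy: str = "mean",
                   coding: str = "auto") -> GenotypeMatrix:
    """Convert biallelic genotype calls to the {-1, 0, +1} coded matrix.

    Parameters
    ----------
    calls
        n x m array-like.  Numeric entries are interpreted as allele
        dosages in {0, 1, 2} (shifted by -1) unless the array already
        contains negative values, in which case it is taken as coded;
        ``nan`` marks missing.  String entries may be genotype labels
        (``A1A1``/``A1A2``/``A2A2``) or VCF GT fields (``0/1``, ``1|1``,
        ``./.``).
    missing_policy
        ``"mean"`` (default) imputes the per-marker mean of observed
        codes; ``"error"`` raises on any missing call.
    coding
        ``"auto"`` detects by value range (any negative value means
        coded, any value > 1 means dosage); ``"codes"`` or ``"dosage"``
        force the interpretation of numeric input.
    """
    if coding not in ("auto", "codes", "dosage"):
        raise ValueError(f"unknown coding {coding!r}")
    arr = np.asarray(calls)
    if arr.ndim != 2:
        raise ValueError("calls must be a 2-D array")
    if arr.dtype.kind in "fiu":
        numeric = arr.astype(float)
        finite = numeric[np.isfinite(numeric)]
        if coding == "dosage":
            numeric = numeric - 1.0
        elif coding == "auto" and finite.size and finite.min() >= 0 \
                and finite.max() > 1:
            numeric = numeric - 1.0  # dosage 0/1/2 -> code -1/0/+1
    else:
        numeric = np.empty(arr.shape, dtype=float)
        dosage_like = False
        for idx, raw in np.ndenumerate(arr):
            s = str(raw).strip()
            if s in _GT_MISSING:
                numeric[idx] = np.nan
            elif s in _GT_CODES:
                numeric[idx] = _GT_CODES[s]
                dosage_like = dosage_like or "/" in s or "|" in s
            else:
                raise ValueError(f"non-biallelic or unrecognized call {s!r}")
        if dosage_like:
            numeric = numeric - 1.0

    n, m = numeric.shape
    individual_ids = list(individual_ids) if individual_ids is not None \
        else [f"ind{i + 1}" for i in range(n)]
    marker_ids = list(marker_ids) if marker_ids is not None \
        else [f"m{k + 1}" for k in range(m)]

    missing = ~np.isfinite(numeric)
    if missing.any():
        if missing_policy == "error":
            raise ValueError("missing genotype calls present")
        if missing_policy != "mean":
            raise ValueError(f"unknown missing policy {missing_policy!r}")
        all_missing = missing.all(axis=0)
        if all_missing.any():
            bad = marker_ids[int(np.argmax(all_missing))]
            raise ValueError(f"marker {bad!r} has no observed calls")
        col_mean = np.nanmean(np.where(missing, np.nan, numeric), axis=0)
        numeric = np.where(missing, col_mean[None, :], numeric)

    return GenotypeMatrix(individual_ids, marker_ids, numeric)


def compute_kinship(geno: GenotypeMatrix, center: bool = False,
                    standardize: bool = False) -> KinshipEigen:
    """Build A = (1/a) Z Z^T with a = tr(Z Z^T)/n (eigen part deferred).

    ``center`` subtracts the per-marker mean before the cross-product;
    ``standardize`` additionally scales each marker to unit variance
    (zero-variance markers are dropped with a warning).  The default uses
    the raw codes.
    """
    Z = geno.codes.copy()
    dropped: list[str] = []
    if center or standardize:
        Z = Z - Z.mean(axis=0, keepdims=True)
    if standardize:
        sd = Z.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            dropped = [mid for mid, k in zip(geno.marker_ids, keep) if not k]
            logger.warning("dropping %d zero-variance markers under "
                           "standardization: %s", len(dropped), dropped[:10])
            Z = Z[:, keep]
            sd = sd[keep]
            if Z.shape[1] == 0:
                raise ValueError("degenerate genotype matrix: no marker "
                                 "has variance")
        Z = Z / sd

    ZZt = Z @ Z.T
    a = float(np.trace(ZZt)) / geno.n
    if a <= 0:
        raise ValueError("degenerate genotype matrix")
    A = ZZt / a
    return KinshipEigen(A=A, a=a, individual_ids=list(geno.individual_ids),
                        dropped_markers=dropped)


def eigendecompose(kin, clip_rel: float = 1e-8,
                   asym_tol: float = 1e-8) -> KinshipEigen:
    """Fill U, D of a :class:`KinshipEigen` (or wrap a bare matrix).

    Eigenvalues are sorted descending; values within ``clip_rel`` times
    the largest eigenvalue of zero are clipped to 0 (the shrinkage factor
    d/(d+lambda) tolerates exact zeros but not negatives).
    """
    global EIGEN_COUNT
    if isinstance(kin, np.ndarray):
        kin = KinshipEigen(A=np.asarray(kin, dtype=float),
                           a=float(np.trace(kin)) / kin.shape[0])
    A = np.asarray(kin.A, dtype=float)
    if not np.isfinite(A).all():
        raise ValueError("non-finite entries in kinship matrix")
    asym = np.abs(A - A.T).max()
    scale = max(np.abs(A).max(), 1.0)
    if asym > asym_tol * scale:
        raise ValueError(f"kinship matrix asymmetric beyond tolerance "
                         f"(max |A - A^T| = {asym:.3g})")
    A = (A + A.T) / 2.0

    D, U = np.linalg.eigh(A)
    EIGEN_COUNT += 1
    order = np.argsort(D)[::-1]
    D, U = D[order], U[:, order]
    floor = -clip_rel * max(D[0], 1.0)
    if D[-1] < floor:
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue "
                         f"{D[-1]:.3g})")
    if D[-1] < -1e-12 * max(D[0], 1.0):
        warnings.warn("clipping tiny negative eigenvalues to zero",
                      stacklevel=2)
    D = np.clip(D, 0.0, None)
    kin.A, kin.U, kin.D = A, U, D
    return kin
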