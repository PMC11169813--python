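"""Differential-geometry primitives on the manifold of SPD matrices.

The log-Euclidean metric (LEM) turns the curved SPD manifold into a flat
Euclidean space in the matrix-log domain: geodesics, means and distances
all reduce to affine operations on matrix logarithms, so the Frechet mean
has a closed form.  The affine-invariant metric (AIRM) is provided as the
iterative baseline: its distance uses the eigenvalues of ``X1^{-1} X2``
and its mean requires a fixed-point (Karcher) iteration.

All matrix functions go through a symmetric eigendecomposition; inputs
are symmetrized as ``(X + X^T)/2`` before decomposing, which guarantees a
real spectrum.  Eigenvalues below ``EIG_FLOOR * lambda_max`` raise
:class:`~spdalign.exceptions.SingularMatrixError` rather than being
clipped silently; use :func:`regularize` to opt in to ridge loading.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .data import SPDDataset
from .exceptions import (
    ConvergenceError,
    DimensionMismatchError,
    InvalidInputError,
    NotSymmetricError,
    SingularMatrixError,
)

__all__ = [
    "SYM_TOL",
    "EIG_FLOOR",
    "check_symmetric",
    "symmetrize",
    "regularize",
    "is_spd",
    "sym_logm",
    "sym_expm",
    "lem_distance",
    "airm_distance",
    "lem_mean",
    "airm_mean",
    "dispersion",
    "lem_geodesic",
    "lem_exp_map",
    "lem_log_map",
    "lem_group_op",
    "spd_power",
    "spd_invsqrt",
]

#: relative symmetry tolerance: max|X - X^T| <= SYM_TOL * max|X|
SYM_TOL = 1e-10
#: relative eigenvalue floor for the positive-definiteness check
EIG_FLOOR = 1e-12


def _as_square(X, name: str = "matrix") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise InvalidInputError(f"{name} must be square, got shape {X.shape}")
    return X


def check_symmetric(X, tol: float = SYM_TOL, name: str = "matrix") -> np.ndarray:
    """Validate symmetry to relative tolerance ``tol`` and return ``X``."""
    X = _as_square(X, name)
    scale = max(np.abs(X).max(), np.finfo(float).tiny)
    asym = np.abs(X - X.T).max()
    if asym > tol * scale:
        raise NotSymmetricError(
            f"{name} is not symmetric: max|X - X^T| = {asym:.3e} "
            f"exceeds {tol:.0e} * max|X| = {tol * scale:.3e}"
        )
    return X


def symmetrize(X) -> np.ndarray:
    """Return ``(X + X^T) / 2``."""
    X = _as_square(X)
    return (X + X.T) / 2.0


def regularize(X, epsilon: float | None = None) -> np.ndarray:
    """Ridge-load ``X`` with ``epsilon * I``.

    ``epsilon`` defaults to ``1e-10 * trace(X) / n``.  This is the opt-in
    escape hatch for rank-deficient covariances; nothing in this module
    clips eigenvalues silently.
    """
    X = _as_square(X)
    n = X.shape[0]
    if epsilon is None:
        epsilon = 1e-10 * np.trace(X) / n
    return X + epsilon * np.eye(n)


def _spd_eigh(X, name: str = "matrix") -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose a symmetric matrix, enforcing positive definiteness."""
    X = check_symmetric(X, name=name)
    w, U = np.linalg.eigh(symmetrize(X))
    floor = EIG_FLOOR * max(w[-1], 0.0)
    if w[0] <= floor:
        raise SingularMatrixError(
            f"{name} is not positive definite: smallest eigenvalue "
            f"{w[0]:.6e} is at or below the floor {floor:.6e}"
        )
    return w, U


def is_spd(X) -> bool:
    """True when ``X`` passes the symmetry and positive-definiteness checks."""
    try:
        _spd_eigh(X)
        return True
    except (InvalidInputError, SingularMatrixError):
        return False


def sym_logm(X) -> np.ndarray:
    """Matrix logarithm of an SPD matrix via eigendecomposition.

    Returns ``U diag(ln lambda_i) U^T``; the result is symmetric.
    """
    w, U = _spd_eigh(X)
    return symmetrize((U * np.log(w)) @ U.T)


def sym_expm(S) -> np.ndarray:
    """Matrix exponential of a symmetric matrix; the inverse of
    :func:`sym_logm`.  The result is SPD."""
    S = check_symmetric(S)
    w, U = np.linalg.eigh(symmetrize(S))
    return symmetrize((U * np.exp(w)) @ U.T)


def _check_same_dim(X1, X2) -> None:
    if X1.shape != X2.shape:
        raise DimensionMismatchError(
            f"operands have shapes {X1.shape} and {X2.shape}"
        )


def lem_distance(X1, X2) -> float:
    """Log-Euclidean distance: Frobenius norm of ``log X2 - log X1``."""
    X1 = _as_square(X1, "X1")
    X2 = _as_square(X2, "X2")
    _check_same_dim(X1, X2)
    return float(np.linalg.norm(sym_logm(X2) - sym_logm(X1), "fro"))


def airm_distance(X1, X2) -> float:
    """Affine-invariant distance: ``sqrt(sum_k ln^2 lambda_k)`` over the
    eigenvalues of ``X1^{-1} X2``.

    Invariant under congruence ``X -> A X A^T`` for any invertible ``A``.
    """
    X1 = check_symmetric(X1, name="X1")
    X2 = check_symmetric(X2, name="X2")
    _check_same_dim(X1, X2)
    _spd_eigh(X1, "X1")  # singular X1 must raise, not silently fail below
    # generalized problem X2 v = lambda X1 v <=> eigenvalues of X1^{-1} X2
    w = scipy.linalg.eigvalsh(symmetrize(X2), symmetrize(X1))
    if np.any(w <= 0):
        raise SingularMatrixError(
            f"X2 is not positive definite: generalized eigenvalue {w[0]:.6e}"
        )
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def _matrix_stack(dataset) -> np.ndarray:
    """Accept an SPDDataset, a (N, n, n) array, or a sequence of matrices."""
    if isinstance(dataset, SPDDataset):
        return dataset.matrices
    arr = np.asarray(dataset, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise InvalidInputError(f"expected a stack of square matrices, got {arr.shape}")
    if len(arr) == 0:
        raise InvalidInputError("empty dataset")
    return arr


def log_stack(dataset) -> np.ndarray:
    """Matrix logarithm of every item in a stack."""
    mats = _matrix_stack(dataset)
    return np.stack([sym_logm(X) for X in mats])


def lem_mean(dataset) -> np.ndarray:
    """Closed-form log-Euclidean Frechet mean: ``exp(mean_i log X_i)``."""
    return sym_expm(log_stack(dataset).mean(axis=0))


def airm_mean(
    dataset,
    tol: float = 1e-8,
    max_iter: int = 100,
    return_info: bool = False,
):
    """Karcher (Frechet) mean under the affine-invariant metric.

    Deterministic full-batch fixed-point iteration::

        M <- M^{1/2} exp( mean_i log(M^{-1/2} X_i M^{-1/2}) ) M^{1/2}

    until the Frobenius norm of the mean log term drops to ``tol``.
    Initialized at the log-Euclidean mean.  With ``return_info=True``
    returns ``(M, info)`` where ``info`` has keys ``iterations`` and
    ``residual``.
    """
    mats = _matrix_stack(dataset)
    M = lem_mean(mats)
    residual = np.inf
    for iteration in range(1, max_iter + 1):
        w, U = _spd_eigh(M, "running mean")
        M_half = (U * np.sqrt(w)) @ U.T
        M_invh = (U / np.sqrt(w)) @ U.T
        mean_log = np.mean(
            [sym_logm(symmetrize(M_invh @ X @ M_invh)) for X in mats], axis=0
        )
        residual = float(np.linalg.norm(mean_log, "fro"))
        if residual <= tol:
            if return_info:
                return M, {"iterations": iteration, "residual": residual}
            return M
        M = symmetrize(M_half @ sym_expm(mean_log) @ M_half)
    raise ConvergenceError(
        f"Karcher mean did not converge in {max_iter} iterations "
        f"(residual {residual:.3e} > tol {tol:.0e})",
        residual=residual,
    )


def dispersion(dataset, center, metric: str = "lem", normalize: str = "sum") -> float:
    """Sum (or mean) of squared geodesic distances of a sample around
    ``center`` — the manifold analogue of a variance.

    ``normalize='sum'`` matches the raw-total convention, ``'mean'`` the
    per-item one; the stretch factor of the alignment module uses ratios
    so either works there, but callers must choose explicitly.
    """
    mats = _matrix_stack(dataset)
    center = _as_square(center, "center")
    if center.shape[0] != mats.shape[1]:
        raise DimensionMismatchError(
            f"center has dimension {center.shape[0]}, dataset has {mats.shape[1]}"
        )
    if metric == "lem":
        log_c = sym_logm(center)
        sq = [np.linalg.norm(sym_logm(X) - log_c, "fro") ** 2 for X in mats]
    elif metric == "airm":
        sq = [airm_distance(center, X) ** 2 for X in mats]
    else:
        raise InvalidInputError(f"unknown metric {metric!r}")
    total = float(np.sum(sq))
    if normalize == "sum":
        return total
    if normalize == "mean":
        return total / len(mats)
    raise InvalidInputError(f"unknown normalization {normalize!r}")


def lem_geodesic(X1, X2, t: float) -> np.ndarray:
    """Point at parameter ``t`` on the LEM geodesic from ``X1`` to ``X2``:
    ``exp((1 - t) log X1 + t log X2)``."""
    X1 = _as_square(X1, "X1")
    X2 = _as_square(X2, "X2")
    _check_same_dim(X1, X2)
    if t == 0.0:
        return X1.copy()
    if t == 1.0:
        return X2.copy()
    return sym_expm((1.0 - t) * sym_logm(X1) + t * sym_logm(X2))


def lem_exp_map(X, V) -> np.ndarray:
    """LEM Riemannian exponential map: ``exp(log X + X^{-1} V)``.

    For tangent vectors produced by :func:`lem_log_map` the inner term
    ``X^{-1} V`` is symmetric and the eigendecomposition route applies;
    otherwise the general matrix exponential is used on the (possibly
    non-symmetric) argument, following the defining formula directly.
    """
    X = _as_square(X, "X")
    V = _as_square(V, "V")
    _check_same_dim(X, V)
    inner = sym_logm(X) + np.linalg.solve(X, V)
    scale = max(np.abs(inner).max(), np.finfo(float).tiny)
    if np.abs(inner - inner.T).max() <= 1e-8 * scale:
        return sym_expm(symmetrize(inner))
    return scipy.linalg.expm(inner)


def lem_log_map(X1, X2) -> np.ndarray:
    """LEM Riemannian logarithmic map: ``X1 (log X2 - log X1)``.

    The initial velocity of the geodesic from ``X1`` to ``X2``; satisfies
    ``<V, V>_{X1} = Tr(X1^{-1} V X1^{-1} V) = lem_distance(X1, X2)^2``.
    """
    X1 = _as_square(X1, "X1")
    X2 = _as_square(X2, "X2")
    _check_same_dim(X1, X2)
    return X1 @ (sym_logm(X2) - sym_logm(X1))


def lem_group_op(X1, X2) -> np.ndarray:
    """Commutative Lie-group operation ``X1 (.) X2 = exp(log X1 + log X2)``."""
    X1 = _as_square(X1, "X1")
    X2 = _as_square(X2, "X2")
    _check_same_dim(X1, X2)
    return sym_expm(sym_logm(X1) + sym_logm(X2))


def spd_power(X, s: float) -> np.ndarray:
    """Matrix power ``X^s = U diag(lambda_i^s) U^T``; ``log(X^s) = s log X``."""
    w, U = _spd_eigh(X)
    return symmetrize((U * w**s) @ U.T)


def spd_invsqrt(X) -> np.ndarray:
    """Convenience alias for ``spd_power(X, -0.5)``."""
    return spd_power(X, -0.5)
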