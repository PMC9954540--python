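"""Super-trial correlation matrices and tangent-space vectorization.

A super-trial stacks the filtered class prototype on top of the filtered
epoch; its correlation matrix is symmetric positive-definite (after light
shrinkage) and lives on the SPD manifold equipped with the affine-invariant
metric. Matrices are projected to Euclidean vectors at the Riemannian
(Karcher) mean; upper-triangular half-vectorization with sqrt(2) off-diagonal
weighting makes the vector norm equal the affine-invariant distance to the
base point.

All matrix functions accept stacked inputs of shape (..., n, n).
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import ConvergenceError, DimensionError, ParameterError, SPDError

_JITTER = 1e-12


def validate_spd(mat: np.ndarray, tol: float = 1e-10, correlation: bool = False) -> None:
    """Raise SPDError unless ``mat`` is symmetric with positive eigenvalues."""
    mat = np.asarray(mat)
    if mat.shape[-1] != mat.shape[-2]:
        raise SPDError(f"matrix is not square: {mat.shape}")
    if not np.allclose(mat, np.swapaxes(mat, -1, -2), atol=tol):
        raise SPDError("matrix is not symmetric")
    eigvals = np.linalg.eigvalsh(mat)
    if np.any(eigvals <= 0):
        raise SPDError(f"matrix has non-positive eigenvalue {eigvals.min()}")
    if correlation and not np.allclose(
        np.diagonal(mat, axis1=-2, axis2=-1), 1.0, atol=1e-6
    ):
        raise SPDError("correlation matrix diagonal is not 1")


def _eigh_fun(mats: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of symmetric matrices."""
    vals, vecs = np.linalg.eigh(mats)
    return (vecs * fun(vals)[..., None, :]) @ np.swapaxes(vecs, -1, -2)


def logm_spd(mats: np.ndarray) -> np.ndarray:
    vals = np.linalg.eigvalsh(mats)
    if np.any(vals <= 0):
        raise SPDError("matrix logarithm requires positive eigenvalues")
    return _eigh_fun(mats, np.log)


def expm_sym(mats: np.ndarray) -> np.ndarray:
    return _eigh_fun(mats, np.exp)


def powm_spd(mats: np.ndarray, power: float) -> np.ndarray:
    vals = np.linalg.eigvalsh(mats)
    if np.any(vals <= 0):
        raise SPDError("matrix power requires positive eigenvalues")
    return _eigh_fun(mats, lambda v: np.power(v, power))


def build_supertrial(filtered_epoch: np.ndarray, prototype: np.ndarray) -> np.ndarray:
    """Stack the prototype rows above the epoch rows.

    ``filtered_epoch`` may be a single (p, T) epoch or a stack (N, p, T);
    the prototype (p, T) is broadcast over the stack.
    """
    filtered_epoch = np.asarray(filtered_epoch, dtype=float)
    prototype = np.asarray(prototype, dtype=float)
    if filtered_epoch.shape[-1] != prototype.shape[-1]:
        raise DimensionError(
            f"sample counts differ: epoch {filtered_epoch.shape[-1]}, "
            f"prototype {prototype.shape[-1]}"
        )
    if filtered_epoch.ndim == 2:
        return np.concatenate([prototype, filtered_epoch], axis=0)
    proto = np.broadcast_to(
        prototype, (filtered_epoch.shape[0],) + prototype.shape
    )
    return np.concatenate([proto, filtered_epoch], axis=1)


def correlation_spd(
    supertrial: np.ndarray,
    shrinkage: float = 1e-6,
    center: bool = True,
) -> np.ndarray:
    """Row-correlation matrix of a super-trial, shrunk toward identity.

    Shrinkage ``(1 - eps) * C + eps * I`` guarantees eigenvalues >= eps.
    Constant rows receive a deterministic 1e-12 jitter (with a warning) so
    the correlation stays defined.
    """
    x = np.asarray(supertrial, dtype=float)
    if x.shape[-1] < 2:
        raise ParameterError("need >= 2 samples to form a correlation matrix")
    if not 0 <= shrinkage < 1:
        raise ParameterError(f"shrinkage must be in [0, 1), got {shrinkage}")
    single = x.ndim == 2
    if single:
        x = x[None]
    if center:
        x = x - x.mean(axis=-1, keepdims=True)
    std = x.std(axis=-1)
    if np.any(std == 0):
        warnings.warn(
            "constant row in super-trial; adding 1e-12 jitter", stacklevel=2
        )
        n_t = x.shape[-1]
        jitter = _JITTER * np.sin(2 * np.pi * np.arange(1, n_t + 1) / (n_t + 1))
        x = np.where((std == 0)[..., None], x + jitter, x)
        if center:
            x = x - x.mean(axis=-1, keepdims=True)
        std = x.std(axis=-1)
    xn = x / std[..., None]
    corr = (xn @ np.swapaxes(xn, -1, -2)) / x.shape[-1]
    n = corr.shape[-1]
    out = (1.0 - shrinkage) * corr + shrinkage * np.eye(n)
    out = 0.5 * (out + np.swapaxes(out, -1, -2))
    return out[0] if single else out


def riemann_mean(
    matrices: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Karcher mean of SPD matrices under the affine-invariant metric.

    Fixed-point iteration M <- M^1/2 exp(mean_i log(M^-1/2 A_i M^-1/2)) M^1/2
    started at the arithmetic mean; the Frobenius norm of the tangent-space
    gradient must drop below ``tol`` within ``max_iter`` iterations.
    """
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    if mats.shape[0] == 0:
        raise ParameterError("riemann_mean requires a non-empty list")
    if mats.shape[-1] != mats.shape[-2]:
        raise DimensionError(f"matrices are not square: {mats.shape}")
    if mats.shape[0] == 1:
        return mats[0].copy()

    mean = mats.mean(axis=0)
    for _ in range(max_iter):
        isq = powm_spd(mean, -0.5)
        sq = powm_spd(mean, 0.5)
        whitened = isq @ mats @ isq
        tangent = logm_spd(whitened).mean(axis=0)
        grad_norm = np.linalg.norm(tangent)
        if grad_norm < tol:
            return mean
        mean = sq @ expm_sym(tangent) @ sq
        mean = 0.5 * (mean + mean.T)
    raise ConvergenceError(
        f"Karcher mean did not converge in {max_iter} iterations "
        f"(last gradient norm {grad_norm:.3e})"
    )


def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n)


def tangent_project(matrix: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Project SPD matrices to tangent vectors at ``base``.

    Returns the upper-triangular half-vectorization of
    log(base^-1/2 M base^-1/2) with off-diagonal entries scaled by sqrt(2),
    so the Euclidean norm equals the affine-invariant distance to the base.
    Accepts a single (n, n) matrix or a stack (N, n, n).
    """
    matrix = np.asarray(matrix, dtype=float)
    base = np.asarray(base, dtype=float)
    if matrix.shape[-1] != base.shape[-1]:
        raise DimensionError(
            f"matrix size {matrix.shape[-1]} != base size {base.shape[-1]}"
        )
    isq = powm_spd(base, -0.5)
    logw = logm_spd(isq @ matrix @ isq)
    n = base.shape[-1]
    rows, cols = _triu_indices(n)
    weights = np.where(rows == cols, 1.0, np.sqrt(2.0))
    return logw[..., rows, cols] * weights


def tangent_unproject(vector: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Exact inverse of tangent_project (exp map back to the manifold)."""
    vector = np.asarray(vector, dtype=float)
    base = np.asarray(base, dtype=float)
    n = base.shape[-1]
    rows, cols = _triu_indices(n)
    if vector.shape[-1] != len(rows):
        raise DimensionError(
            f"vector length {vector.shape[-1]} != n(n+1)/2 = {len(rows)}"
        )
    weights = np.where(rows == cols, 1.0, np.sqrt(2.0))
    sym = np.zeros(vector.shape[:-1] + (n, n))
    sym[..., rows, cols] = vector / weights
    sym = sym + np.swapaxes(sym, -1, -2)
    sym[..., np.arange(n), np.arange(n)] /= 2.0
    sq = powm_spd(base, 0.5)
    return sq @ expm_sym(sym) @ sq


def flatten_reduced(corr: np.ndarray, prototype_rows: int) -> np.ndarray:
    """Unique off-diagonal entries with the prototype block removed.

    Keeps the prototype-epoch cross block (row-major) followed by the upper
    triangle of the epoch-epoch block; drops the diagonal and every entry of
    the prototype-prototype block, which depends on the prototype alone.
    Accepts a single matrix or a stack.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[-1]
    p = int(prototype_rows)
    if p >= n:
        raise DimensionError(f"prototype_rows={p} must be < matrix size {n}")
    cross = corr[..., :p, p:].reshape(corr.shape[:-2] + (p * (n - p),))
    rows, cols = np.triu_indices(n - p, k=1)
    epoch_block = corr[..., p:, p:][..., rows, cols]
    return np.concatenate([cross, epoch_block], axis=-1)
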