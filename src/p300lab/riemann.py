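"""Affine-invariant Riemannian distance and the minimum-distance-to-mean
(MDM) baseline classifier."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import ClassError, DimensionError, SPDError
from .spd import riemann_mean, validate_spd


def aird(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices.

    sqrt of the sum of squared logs of the generalized eigenvalues of
    (a, b); symmetric, zero iff a == b, invariant under congruence
    a -> G a G^T, b -> G b G^T.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"size mismatch: {a.shape} vs {b.shape}")
    validate_spd(a)
    validate_spd(b)
    eigvals = linalg.eigvalsh(a, b)
    if np.any(eigvals <= 0):
        raise SPDError("generalized eigenvalues not positive")
    return float(np.sqrt(np.sum(np.log(eigvals) ** 2)))


def _dist_to_base(matrices: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Batched affine-invariant distance of a stack of SPD matrices to one
    base point (no per-matrix validation; used on trusted pipeline output)."""
    from .spd import logm_spd, powm_spd

    isq = powm_spd(base, -0.5)
    logs = logm_spd(isq @ matrices @ isq)
    return np.sqrt(np.sum(logs**2, axis=(-2, -1)))


@dataclass
class MDMModel:
    class_means: dict  # class -> SPD mean matrix
    classes: np.ndarray  # classes in training order (first occurrence)


def mdm_fit(matrices: np.ndarray, labels: np.ndarray,
            tol: float = 1e-8, max_iter: int = 50) -> MDMModel:
    """Karcher mean per class; class order follows first occurrence in
    ``labels`` (used for tie-breaking at predict time)."""
    matrices = np.asarray(matrices, dtype=float)
    labels = np.asarray(labels)
    classes = labels[np.sort(np.unique(labels, return_index=True)[1])]
    if len(classes) < 1:
        raise ClassError("no classes in labels")
    means = {}
    for cls in classes:
        member = matrices[labels == cls]
        if len(member) < 1:
            raise ClassError(f"class {cls!r} has no matrices")
        means[cls] = riemann_mean(member, tol=tol, max_iter=max_iter)
    return MDMModel(class_means=means, classes=classes)


def mdm_predict(model: MDMModel, matrix: np.ndarray):
    """Argmin-distance class; exact ties go to the first training class.

    ``matrix`` may be a single (n, n) SPD matrix or a stack (N, n, n), in
    which case an array of classes is returned.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = next(iter(model.class_means.values())).shape[-1]
    if matrix.shape[-1] != n:
        raise DimensionError(
            f"matrix size {matrix.shape[-1]} does not match training size {n}"
        )
    single = matrix.ndim == 2
    stack = matrix[None] if single else matrix
    dists = np.stack(
        [_dist_to_base(stack, model.class_means[cls]) for cls in model.classes]
    )  # (n_classes, N)
    winners = model.classes[np.argmin(dists, axis=0)]  # argmin takes first on ties
    return winners[0] if single else winners


class MDM:
    """scikit-learn style wrapper over mdm_fit / mdm_predict."""

    def __init__(self, tol: float = 1e-8, max_iter: int = 50):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, matrices: np.ndarray, labels: np.ndarray) -> "MDM":
        self.model_ = mdm_fit(matrices, labels, tol=self.tol,
                              max_iter=self.max_iter)
        return self

    def predict(self, matrices: np.ndarray) -> np.ndarray:
        return np.atleast_1d(mdm_predict(self.model_, matrices))
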