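"""Per-class spatial filters maximizing evoked-to-signal variance ratio.

For each class the leading generalized eigenvectors of
(covariance of the class-average evoked response, covariance of the whole
signal) are taken as spatial filters. With one filter per class and two
classes, a filtered epoch has 2 rows, which with a 2-row filtered prototype
yields the 4x4 super-trial correlation matrices downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import ClassError, DimensionError
from .synth import EpochSet


@dataclass
class XdawnModel:
    """Fitted spatial filters and evoked prototypes, one set per class."""

    filters: dict  # class -> (nfilter, n_channels) array, unit-norm rows
    prototypes: dict  # class -> (n_channels, n_samples) mean evoked response
    classes: np.ndarray  # ordered class list

    @property
    def n_channels(self) -> int:
        first = self.filters[self.classes[0]]
        return first.shape[1]


def fit_xdawn(
    epochs: EpochSet | np.ndarray,
    labels: np.ndarray | None = None,
    nfilter: int = 1,
    loading: float = 1e-8,
) -> XdawnModel:
    """Estimate per-class spatial filters from labelled epochs.

    Parameters
    ----------
    epochs : EpochSet, or raw (n_trials, n_channels, n_samples) array with
        ``labels`` given separately.
    nfilter : filters kept per class (descending eigenvalue order).
    loading : diagonal loading added to the signal covariance.
    """
    if isinstance(epochs, EpochSet):
        data, labels = epochs.data, epochs.labels
    else:
        data = np.asarray(epochs, dtype=float)
        if labels is None:
            raise ClassError("labels required when epochs is a raw array")
    labels = np.asarray(labels)
    n_trials, n_channels, n_samples = data.shape
    if nfilter > n_channels:
        raise DimensionError(
            f"nfilter={nfilter} exceeds channel count {n_channels}"
        )

    classes = np.unique(labels)
    if len(classes) < 2:
        raise ClassError(f"need >= 2 classes, got {classes!r}")

    # signal covariance from concatenated epochs, shared across classes
    concat = data.transpose(1, 0, 2).reshape(n_channels, -1)
    c_signal = np.cov(concat) + loading * np.eye(n_channels)

    filters, prototypes = {}, {}
    for cls in classes:
        member = data[labels == cls]
        if len(member) < 2:
            raise ClassError(f"class {cls!r} has fewer than 2 epochs")
        proto = member.mean(axis=0)
        c_evoked = np.cov(proto)
        eigvals, eigvecs = linalg.eigh(c_evoked, c_signal)
        w = eigvecs[:, ::-1][:, :nfilter].T  # descending eigenvalue order
        w = w / np.linalg.norm(w, axis=1, keepdims=True)
        # sign convention: largest-magnitude coefficient positive
        for row in w:
            row *= np.sign(row[np.argmax(np.abs(row))]) or 1.0
        filters[cls] = w
        prototypes[cls] = proto
    return XdawnModel(filters=filters, prototypes=prototypes, classes=classes)


def save_xdawn(model: XdawnModel, path) -> None:
    """Serialize a fitted model to the package's archive format."""
    from .synth import _write_archive
    from pathlib import Path

    arrays = {"classes": np.asarray(model.classes)}
    for i, cls in enumerate(model.classes):
        arrays[f"filters_{i}"] = model.filters[cls]
        arrays[f"prototypes_{i}"] = model.prototypes[cls]
    _write_archive(Path(path), arrays, {"kind": "xdawn"})


def load_xdawn(path) -> XdawnModel:
    from .exceptions import FormatError
    from .synth import _read_archive
    from pathlib import Path

    arrays, meta = _read_archive(Path(path))
    if meta.get("kind") != "xdawn" or "classes" not in arrays:
        raise FormatError("archive does not hold an xDAWN model")
    classes = arrays["classes"]
    filters = {cls: arrays[f"filters_{i}"] for i, cls in enumerate(classes)}
    prototypes = {cls: arrays[f"prototypes_{i}"] for i, cls in enumerate(classes)}
    return XdawnModel(filters=filters, prototypes=prototypes, classes=classes)


def stacked_filters(model: XdawnModel) -> np.ndarray:
    """All classes' filters stacked, class order as in ``model.classes``."""
    return np.vstack([model.filters[cls] for cls in model.classes])


def apply_filters(model: XdawnModel, epoch: np.ndarray) -> np.ndarray:
    """Project an epoch (or stack of epochs) onto the virtual channels.

    Output rows are the concatenation of every class's filters, so a single
    epoch maps from (n_channels, T) to (nfilter * n_classes, T).
    """
    epoch = np.asarray(epoch, dtype=float)
    w = stacked_filters(model)
    if epoch.shape[-2] != w.shape[1]:
        raise DimensionError(
            f"epoch has {epoch.shape[-2]} channels, filters expect {w.shape[1]}"
        )
    return w @ epoch
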