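"""Hypergraph case-based reasoning binary classifier.

Feature vectors are discretized into *cases*: sets of (feature index,
rounded value) tokens. Cases are the edges of a hypergraph; tokens that
belong to exactly the same set of cases form one cell of the partition.
The model is s = W mu where row j of W holds the fractions of case j's
tokens falling in each cell (||w_j||_1 = 1) and mu is a signed per-cell
intrinsic strength with ||mu||_1 = 1. A query's support is the convex
combination of mu weighted by its overlap with the cells; its sign is the
predicted class. A query intersecting no cell yields an abstention and the
default (majority training) class.

The mu initialization and the post-hoc correction passes (l0 of them, step
eta along the misclassified case's W row) are reconstructions exposed as
configuration; only l0 is meant to be tuned, matching a setup where every
other hyperparameter stays at its inert default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ClassError, ParameterError

Token = tuple[int, float]


@dataclass(frozen=True)
class Case:
    """Discrete token set plus (optional) label."""

    elements: frozenset
    label: object = None

    def __post_init__(self):
        if not self.elements:
            raise ParameterError("a case must contain at least one token")


def discretize(vector: np.ndarray, digits: int = 4, label: object = None) -> Case:
    """Round a real vector into a token-set case.

    Tokens are (feature index, value rounded to ``digits`` decimals), so the
    case cardinality always equals the vector length.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1:
        raise ParameterError(f"expected 1-d vector, got shape {vector.shape}")
    if not np.all(np.isfinite(vector)):
        raise ParameterError("vector contains NaN or infinite entries")
    rounded = np.round(vector, digits) + 0.0  # +0.0 folds -0.0 into 0.0
    tokens = frozenset((int(i), float(v)) for i, v in enumerate(rounded))
    return Case(elements=tokens, label=label)


def build_hypergraph(cases: list[Case]) -> list[frozenset]:
    """Partition all observed tokens by identical case-membership signature.

    Two tokens share a cell iff they belong to exactly the same set of
    cases; the result covers every token, cells pairwise disjoint, and is
    invariant to the order of ``cases``.
    """
    if not cases:
        raise ParameterError("need at least one case")
    membership: dict[Token, frozenset] = {}
    token_sets = [case.elements for case in cases]
    all_tokens = set().union(*token_sets)
    for token in all_tokens:
        sig = frozenset(j for j, s in enumerate(token_sets) if token in s)
        membership[token] = sig
    cells: dict[frozenset, set] = {}
    for token, sig in membership.items():
        cells.setdefault(sig, set()).add(token)
    # canonical (order-independent) cell ordering
    return sorted((frozenset(c) for c in cells.values()), key=sorted)


@dataclass
class HypergraphModel:
    partition: list  # list of frozenset cells
    W: np.ndarray  # (n_cases, n_cells), rows sum to 1 in absolute value
    mu: np.ndarray  # (n_cells,), ||mu||_1 = 1
    l0: int
    default_class: object
    classes: np.ndarray  # [negative class, positive class]
    token_cell: dict = field(repr=False, default_factory=dict)


def _overlap_row(case: Case, partition: list[frozenset],
                 token_cell: dict) -> np.ndarray:
    row = np.zeros(len(partition))
    inv = 1.0 / len(case.elements)
    for token in case.elements:
        idx = token_cell.get(token)
        if idx is not None:
            row[idx] += inv
    return row


def fit(
    cases: list[Case],
    labels: np.ndarray | list,
    l0: int = 1,
    eta: float = 0.1,
) -> HypergraphModel:
    """Build the partition, W, and mu from labelled cases.

    mu starts from the signed overlap-weighted class balance of the cases
    touching each cell, then ``l0`` correction passes nudge it (step
    ``eta`` along W rows) toward fixing training misclassifications.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cases):
        raise ParameterError("labels and cases differ in length")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ClassError(f"binary classifier needs exactly 2 classes, got {classes!r}")
    if l0 < 0:
        raise ParameterError(f"l0 must be >= 0, got {l0}")
    signs = np.where(labels == classes[1], 1.0, -1.0)

    partition = build_hypergraph(cases)
    token_cell = {tok: i for i, cell in enumerate(partition) for tok in cell}

    w = np.stack([_overlap_row(c, partition, token_cell) for c in cases])
    # training cases are fully covered by the partition: rows sum to 1

    mu = signs @ w  # signed, overlap-weighted class balance per cell
    mu = _l1_normalize(mu)

    for _ in range(l0):
        support = w @ mu
        wrong = np.sign(support) != signs
        if not np.any(wrong):
            break
        mu = mu + eta * (signs[wrong] @ w[wrong])
        mu = _l1_normalize(mu)

    counts = {cls: int(np.sum(labels == cls)) for cls in classes}
    default_class = max(classes, key=lambda c: counts[c])
    return HypergraphModel(
        partition=partition,
        W=w,
        mu=mu,
        l0=l0,
        default_class=default_class,
        classes=classes,
        token_cell=token_cell,
    )


def _l1_normalize(mu: np.ndarray) -> np.ndarray:
    norm = np.sum(np.abs(mu))
    if norm == 0:
        return np.full_like(mu, 1.0 / len(mu))
    return mu / norm


def predict(model: HypergraphModel, case: Case):
    """Return (class, support, abstained).

    support = sum_i overlap(case, cell_i) * mu_i; class is its sign (the
    positive sign maps to ``model.classes[1]``). A case that intersects no
    cell abstains: default class, support 0, abstained True.
    """
    row = _overlap_row(case, model.partition, model.token_cell)
    if not row.any():
        return model.default_class, 0.0, True
    support = float(row @ model.mu)
    if support > 0:
        return model.classes[1], support, False
    if support < 0:
        return model.classes[0], support, False
    return model.default_class, 0.0, False


class HCBR:
    """scikit-learn style wrapper: discretize rows, fit, predict."""

    def __init__(self, digits: int = 4, l0: int = 1, eta: float = 0.1):
        self.digits = digits
        self.l0 = l0
        self.eta = eta

    def fit(self, X: np.ndarray, y: np.ndarray) -> "HCBR":
        cases = [discretize(row, self.digits) for row in np.asarray(X)]
        self.model_ = fit(cases, y, l0=self.l0, eta=self.eta)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = [
            predict(self.model_, discretize(row, self.digits))[0]
            for row in np.asarray(X)
        ]
        return np.asarray(out)
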