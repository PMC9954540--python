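"""Cross-validated evaluation: balanced accuracy, stratified folds,
permutation significance threshold, and the end-to-end experiment runner.

All fold-dependent statistics (xDAWN filters, prototypes, tangent base,
hypergraph, kernel states) are fitted on training folds only; the pipeline
exposes a fingerprint of its fitted state so leakage tests can verify that
refitting on the same training subset reproduces it exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.svm import SVC

from .exceptions import ClassError, ParameterError, StratificationError
from .hcbr import HCBR
from .preprocess import FilterSpec, bandpass, extract_epochs
from .quantum import QSVCClassifier, VQCClassifier
from .riemann import MDM
from .spd import (
    build_supertrial,
    correlation_spd,
    flatten_reduced,
    riemann_mean,
    tangent_project,
)
from .synth import (
    TARGET,
    EpochSet,
    P300Params,
    SessionDesign,
    generate_session,
)
from .xdawn import apply_filters, fit_xdawn


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of the two per-class recalls.

    With A/B the correctly/incorrectly classified members of one class and
    C/D of the other: 0.5 * (A / (A + B) + C / (C + D)).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ParameterError("y_true and y_pred differ in length")
    classes = np.unique(y_true)
    if len(classes) < 2:
        raise ClassError("y_true must contain both classes")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


def stratified_kfold(
    labels: np.ndarray, k: int = 5, seed: int | None = None
) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Within each class, indices are shuffled (seeded) and split into k
    nearly-equal chunks, so per-fold class proportions stay within one
    trial of the global proportions. Returns an int array of fold ids.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise StratificationError(
                f"class {cls!r} has {len(idx)} members, fewer than k={k}"
            )
        idx = rng.permutation(idx)
        for fold, chunk in enumerate(np.array_split(idx, k)):
            folds[chunk] = fold
    return folds


# ---------------------------------------------------------------------------
# feature + classifier pipeline


FEATURE_MODES = ("tangent", "reduced", "epochvec", "matrix")


class ErpPipeline:
    """xDAWN -> super-trial correlation -> features -> classifier.

    ``feature_mode``:
      * ``tangent``  - tangent vectors at the training Riemannian mean
      * ``reduced``  - off-diagonal correlation entries, prototype block
        removed
      * ``epochvec`` - flattened xDAWN-filtered epochs (no correlation step)
      * ``matrix``   - the SPD matrices themselves (MDM input)
    """

    def __init__(self, classifier, feature_mode: str = "tangent",
                 nfilter: int = 1, shrinkage: float = 1e-6):
        if feature_mode not in FEATURE_MODES:
            raise ParameterError(
                f"unknown feature_mode {feature_mode!r}; choose from "
                f"{FEATURE_MODES}"
            )
        self.classifier = classifier
        self.feature_mode = feature_mode
        self.nfilter = nfilter
        self.shrinkage = shrinkage

    # -- fitting ----------------------------------------------------------
    def fit(self, data: np.ndarray, labels: np.ndarray) -> "ErpPipeline":
        data = np.asarray(data, dtype=float)
        labels = np.asarray(labels)
        self.xdawn_ = fit_xdawn(data, labels, nfilter=self.nfilter)
        self.prototype_ = apply_filters(self.xdawn_, self.xdawn_.prototypes[TARGET])
        self.base_ = None
        feats = self._features(data, fit=True)
        self.classifier.fit(feats, labels)
        return self

    def predict(self, data: np.ndarray) -> np.ndarray:
        feats = self._features(np.asarray(data, dtype=float), fit=False)
        return np.asarray(self.classifier.predict(feats))

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Feature matrix for already-fitted filters/base (one row per trial)."""
        return self._features(np.asarray(data, dtype=float), fit=False)

    # -- internals --------------------------------------------------------
    def _matrices(self, data: np.ndarray) -> np.ndarray:
        filtered = np.einsum("vc,ncs->nvs", self._stacked_filters(), data)
        sts = build_supertrial(filtered, self.prototype_)
        return correlation_spd(sts, shrinkage=self.shrinkage)

    def _stacked_filters(self) -> np.ndarray:
        from .xdawn import stacked_filters

        return stacked_filters(self.xdawn_)

    def _features(self, data: np.ndarray, fit: bool) -> np.ndarray:
        if self.feature_mode == "epochvec":
            filtered = np.einsum("vc,ncs->nvs", self._stacked_filters(), data)
            return filtered.reshape(len(data), -1)
        mats = self._matrices(data)
        if self.feature_mode == "matrix":
            return mats
        if self.feature_mode == "reduced":
            return flatten_reduced(mats, prototype_rows=self.prototype_.shape[0])
        if fit:
            self.base_ = riemann_mean(mats)
        return tangent_project(mats, self.base_)

    def fingerprint(self) -> str:
        """Hash of every fitted statistic (leakage/determinism checks)."""
        h = hashlib.sha256()
        h.update(self._stacked_filters().tobytes())
        h.update(self.prototype_.tobytes())
        if self.base_ is not None:
            h.update(self.base_.tobytes())
        return h.hexdigest()


def make_classifier(name: str, seed: int | None = None, **cfg):
    """Instantiate a registered classifier by name."""
    name = name.lower()
    if name == "mdm":
        return MDM(**cfg)
    if name == "svm":
        return SVC(kernel=cfg.pop("kernel", "rbf"), **cfg)
    if name == "hcbr":
        return HCBR(**cfg)
    if name == "vqc":
        return VQCClassifier(seed=seed, **cfg)
    if name == "qsvc":
        return QSVCClassifier(seed=seed, **cfg)
    raise ParameterError(
        f"unknown classifier {name!r}; valid names: hcbr, vqc, qsvc, svm, mdm"
    )


def make_pipeline(name: str, seed: int | None = None, nfilter: int = 1,
                  feature_mode: str | None = None, **cfg) -> ErpPipeline:
    """Default pipeline for a classifier name (MDM consumes matrices, the
    others tangent vectors unless a mode is forced)."""
    if feature_mode is None:
        feature_mode = "matrix" if name.lower() == "mdm" else "tangent"
    clf = make_classifier(name, seed=seed, **cfg)
    return ErpPipeline(clf, feature_mode=feature_mode, nfilter=nfilter)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    classifier: str
    train_scores: list
    test_scores: list
    seed: int | None
    config: dict = field(default_factory=dict)
    fold_fingerprints: list = field(default_factory=list)

    @property
    def mean_test(self) -> float:
        return float(np.mean(self.test_scores))

    @property
    def std_test(self) -> float:
        return float(np.std(self.test_scores))

    @property
    def mean_train(self) -> float:
        return float(np.mean(self.train_scores))

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(mean_test=self.mean_test, std_test=self.std_test,
                 mean_train=self.mean_train)
        return d


def cross_validate(
    pipeline_factory,
    data: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int | None = None,
    name: str = "",
    config: dict | None = None,
) -> CVReport:
    """Stratified k-fold CV; ``pipeline_factory()`` must return a fresh
    pipeline with fit/predict (fitted on the training fold only)."""
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    folds = stratified_kfold(labels, k=k, seed=seed)
    train_scores, test_scores, fingerprints = [], [], []
    for fold in range(k):
        test_mask = folds == fold
        pipe = pipeline_factory()
        pipe.fit(data[~test_mask], labels[~test_mask])
        train_scores.append(
            balanced_accuracy(labels[~test_mask], pipe.predict(data[~test_mask]))
        )
        test_scores.append(
            balanced_accuracy(labels[test_mask], pipe.predict(data[test_mask]))
        )
        if hasattr(pipe, "fingerprint"):
            fingerprints.append(pipe.fingerprint())
    return CVReport(
        classifier=name, train_scores=train_scores, test_scores=test_scores,
        seed=seed, config=config or {}, fold_fingerprints=fingerprints,
    )


# ---------------------------------------------------------------------------
# permutation significance threshold


def permutation_threshold(
    pipeline_factory,
    data: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
    k: int = 5,
    return_scores: bool = False,
):
    """0.975-quantile (for alpha=0.05) of CV test balanced accuracy under
    label permutation; nearest-rank empirical quantile, seeded."""
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    quantile = 1.0 - alpha / 2.0
    scores = np.empty(n_perm)
    for i in range(n_perm):
        permuted = rng.permutation(labels)
        report = cross_validate(
            pipeline_factory, data, permuted, k=k,
            seed=int(rng.integers(2**31)),
        )
        scores[i] = report.mean_test
    ordered = np.sort(scores)
    rank = int(np.ceil(quantile * n_perm)) - 1  # nearest-rank
    threshold = float(ordered[min(max(rank, 0), n_perm - 1)])
    if return_scores:
        return threshold, scores
    return threshold


# ---------------------------------------------------------------------------
# experiment runner


DEFAULT_CONFIG = {
    "seed": 0,
    "design": {},  # SessionDesign overrides
    "amplitude": 5.0,
    "noise_scale": 1.0,
    "low": 1.0,
    "high": 24.0,
    "tmin": 0.1,
    "tmax": 0.7,
    "nfilter": 1,
    "k": 5,
    "classifiers": ["mdm", "svm"],
    "feature_mode": None,  # per-classifier default
    "classifier_options": {},  # name -> kwargs
    "sweep": False,  # digits x nfilter grid for hcbr
    "sweep_digits": [4, 6, 8],
    "sweep_nfilters": [1, 2, 4],
    "permutation": False,
    "n_perm": 200,
    "alpha": 0.05,
}


def _session_epochs(config: dict) -> EpochSet:
    design = SessionDesign(**config.get("design", {}))
    p300 = P300Params(amplitude=config["amplitude"])
    record, onsets, labels = generate_session(
        design, p300, noise_scale=config["noise_scale"], seed=config["seed"]
    )
    spec = FilterSpec(low=config["low"], high=config["high"])
    filtered = bandpass(record, design.sfreq, spec)
    return extract_epochs(filtered, onsets, labels, design.sfreq,
                          tmin=config["tmin"], tmax=config["tmax"])


def run_experiment(config: dict) -> dict:
    """End-to-end run: simulate -> filter -> epoch -> features -> CV.

    Returns {"reports": {name: CVReport}, "table": rows, and optionally
    "sweep" (digits x nfilter grid) and "threshold"}.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    for name in cfg["classifiers"]:
        make_classifier(name, seed=0, **cfg["classifier_options"].get(name, {}))

    epochs = _session_epochs(cfg)
    data, labels = epochs.data, epochs.labels

    reports, rows = {}, []
    for name in cfg["classifiers"]:
        opts = dict(cfg["classifier_options"].get(name, {}))

        def factory(name=name, opts=opts):
            return make_pipeline(
                name, seed=cfg["seed"], nfilter=cfg["nfilter"],
                feature_mode=cfg["feature_mode"], **opts,
            )

        report = cross_validate(
            factory, data, labels, k=cfg["k"], seed=cfg["seed"], name=name,
            config={"nfilter": cfg["nfilter"], **opts},
        )
        reports[name] = report
        rows.append(
            {"classifier": name, "mean_train": report.mean_train,
             "mean_test": report.mean_test, "std_test": report.std_test}
        )

    out = {"reports": reports, "table": rows}

    if cfg["sweep"]:
        out["sweep"] = sweep_hcbr(
            data, labels, digits_grid=cfg["sweep_digits"],
            nfilter_grid=cfg["sweep_nfilters"], k=cfg["k"], seed=cfg["seed"],
        )

    if cfg["permutation"]:
        out["threshold"] = permutation_threshold(
            lambda: make_pipeline("mdm", nfilter=cfg["nfilter"]),
            data, labels, n_perm=cfg["n_perm"], alpha=cfg["alpha"],
            seed=cfg["seed"], k=cfg["k"],
        )
    return out


def sweep_hcbr(
    data: np.ndarray,
    labels: np.ndarray,
    digits_grid=(4, 6, 8),
    nfilter_grid=(1, 2, 4),
    k: int = 5,
    seed: int | None = None,
) -> dict:
    """Hyperparameter grid for the case-based classifier: rounding digits
    by xDAWN filter count; returns mean test balanced accuracy per cell."""
    grid = {}
    for nfilter in nfilter_grid:
        for digits in digits_grid:
            report = cross_validate(
                lambda: make_pipeline("hcbr", nfilter=nfilter, digits=digits),
                data, labels, k=k, seed=seed,
                name=f"hcbr(d={digits},f={nfilter})",
            )
            grid[(nfilter, digits)] = report.mean_test
    return grid


def report_to_json(result: dict) -> str:
    """Serialize a run_experiment result (reports + table + extras)."""
    payload = {
        "table": result["table"],
        "reports": {k: v.to_dict() for k, v in result["reports"].items()},
    }
    if "sweep" in result:
        payload["sweep"] = {f"{nf}x{d}": v for (nf, d), v in result["sweep"].items()}
    if "threshold" in result:
        payload["threshold"] = result["threshold"]
    return json.dumps(payload, indent=1)
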