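"""Exact state-vector simulation of the quantum classifiers.

Second-order Pauli-Z feature map (per repetition: Hadamards, single-qubit
phases 2*x_i, pairwise phases 2*(pi - x_i)*(pi - x_j) on entangled pairs),
fidelity kernel |<phi(x)|phi(y)>|^2 with a soft-margin SVM on top (QSVC),
and a two-local variational circuit (ry/rz rotation layers, cz
entanglement) read out by bitstring parity and trained with SPSA (VQC).

Exact mode is the default everywhere; shot mode draws seeded measurement
samples. Qubit 0 is the least-significant bit of the basis-state index.

The simulator is written for stacks: most helpers accept an (N, 2^n) batch
of state vectors and apply each gate to the whole batch at once, which keeps
10-qubit kernels and VQC training fast in pure numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from sklearn.svm import SVC

from .exceptions import ClassError, DimensionError, ParameterError

# ---------------------------------------------------------------------------
# basis bookkeeping


@lru_cache(maxsize=16)
def _bits(n: int) -> np.ndarray:
    """(2^n, n) matrix of basis-state bits; column q is qubit q (LSB)."""
    z = np.arange(2**n)
    return ((z[:, None] >> np.arange(n)[None, :]) & 1).astype(float)


@lru_cache(maxsize=16)
def _parity_mask(n: int) -> np.ndarray:
    """True where the basis state has even bit parity (label +1)."""
    return _bits(n).sum(axis=1) % 2 == 0


@lru_cache(maxsize=16)
def _hadamard(n: int) -> np.ndarray:
    from scipy.linalg import hadamard

    return hadamard(2**n) / np.sqrt(2.0**n)


def entangler_pairs(n: int, entanglement: str) -> list[tuple[int, int]]:
    if entanglement == "linear":
        return [(i, i + 1) for i in range(n - 1)]
    if entanglement == "full":
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    raise ParameterError(f"unknown entanglement pattern {entanglement!r}")


# ---------------------------------------------------------------------------
# feature map


@dataclass(frozen=True)
class FeatureMapSpec:
    n_features: int
    reps: int = 2
    entanglement: str = "linear"

    def __post_init__(self):
        if self.n_features < 1:
            raise ParameterError("n_features must be >= 1")
        if self.reps < 1:
            raise ParameterError("reps must be >= 1")
        entangler_pairs(max(self.n_features, 2), self.entanglement)


def _feature_phase(x: np.ndarray, spec: FeatureMapSpec) -> np.ndarray:
    """Diagonal phase (radians) applied after the Hadamard layer of one rep."""
    n = spec.n_features
    bits = _bits(n)
    phase = bits @ (2.0 * x)
    for i, j in entangler_pairs(n, spec.entanglement):
        differ = np.abs(bits[:, i] - bits[:, j])  # cx-p-cx acts on XOR = 1
        phase = phase + 2.0 * (np.pi - x[i]) * (np.pi - x[j]) * differ
    return phase


def zz_feature_map(x: np.ndarray, spec: FeatureMapSpec) -> np.ndarray:
    """Encode a real vector as a 2^n state vector."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) != spec.n_features:
        raise DimensionError(
            f"input has {len(x)} features, spec expects {spec.n_features}"
        )
    n = spec.n_features
    state = np.zeros(2**n, dtype=complex)
    state[0] = 1.0
    phase = np.exp(1j * _feature_phase(x, spec))
    h = _hadamard(n)
    for _ in range(spec.reps):
        state = h @ state
        state = state * phase
    return state


def _feature_states(X: np.ndarray, spec: FeatureMapSpec) -> np.ndarray:
    """(N, 2^n) batch of feature-mapped states (vectorized over samples)."""
    X = np.asarray(X, dtype=float)
    n = spec.n_features
    phases = np.exp(1j * np.stack([_feature_phase(x, spec) for x in X]))
    states = np.zeros((len(X), 2**n), dtype=complex)
    states[:, 0] = 1.0
    h = _hadamard(n)  # symmetric, so right-multiplication applies H to all qubits
    for _ in range(spec.reps):
        states = (states @ h) * phases
    return states


# ---------------------------------------------------------------------------
# fidelity kernel


def quantum_kernel(
    x: np.ndarray,
    y: np.ndarray,
    spec: FeatureMapSpec,
    shots: int = 0,
    seed: int | None = None,
) -> float:
    """|<phi(x)|phi(y)>|^2, exact (shots=0) or estimated from measurement
    samples of the fidelity circuit (shots > 0, seeded)."""
    if shots < 0:
        raise ParameterError(f"shots must be >= 0, got {shots}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise DimensionError(f"length mismatch: {len(x)} vs {len(y)}")
    overlap = np.vdot(zz_feature_map(y, spec), zz_feature_map(x, spec))
    p0 = float(np.abs(overlap) ** 2)
    if shots == 0:
        return min(p0, 1.0)
    rng = np.random.default_rng(seed)
    return rng.binomial(shots, min(p0, 1.0)) / shots


def kernel_matrix(
    X: np.ndarray,
    spec: FeatureMapSpec,
    shots: int = 0,
    seed: int | None = None,
    Y: np.ndarray | None = None,
) -> np.ndarray:
    """Gram matrix of the fidelity kernel.

    Exact mode has a unit diagonal and is positive semidefinite. ``Y`` gives
    the cross-kernel K[i, j] = k(X_i, Y_j) used at prediction time.
    """
    if shots < 0:
        raise ParameterError(f"shots must be >= 0, got {shots}")
    states_x = _feature_states(X, spec)
    symmetric = Y is None
    states_y = states_x if symmetric else _feature_states(Y, spec)
    gram = np.abs(states_x @ states_y.conj().T) ** 2
    gram = np.minimum(gram, 1.0)
    if symmetric:
        gram = 0.5 * (gram + gram.T)
        np.fill_diagonal(gram, 1.0)
    if shots:
        rng = np.random.default_rng(seed)
        sampled = rng.binomial(shots, gram) / shots
        if symmetric:
            sampled = np.triu(sampled) + np.triu(sampled, 1).T
            np.fill_diagonal(sampled, 1.0)
        gram = sampled
    return gram


# ---------------------------------------------------------------------------
# QSVC


@dataclass
class QSVCModel:
    spec: FeatureMapSpec
    svc: SVC
    X_train: np.ndarray
    shots: int = 0
    seed: int | None = None


def qsvc_fit(
    X: np.ndarray,
    y: np.ndarray,
    spec: FeatureMapSpec,
    shots: int = 0,
    C: float = 1.0,
    seed: int | None = None,
) -> QSVCModel:
    """Soft-margin SVM on the precomputed quantum kernel."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ClassError("qsvc_fit needs two classes")
    gram = kernel_matrix(X, spec, shots=shots, seed=seed)
    svc = SVC(kernel="precomputed", C=C)
    svc.fit(gram, y)
    return QSVCModel(spec=spec, svc=svc, X_train=X.copy(), shots=shots, seed=seed)


def qsvc_predict(model: QSVCModel, x: np.ndarray) -> np.ndarray:
    """Predict one sample (1-d input) or a batch (2-d input)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    batch = x[None] if single else x
    seed = None if model.seed is None else model.seed + 1
    cross = kernel_matrix(
        batch, model.spec, shots=model.shots, seed=seed, Y=model.X_train
    )
    pred = model.svc.predict(cross)
    return pred[0] if single else pred


# ---------------------------------------------------------------------------
# variational circuit


@dataclass(frozen=True)
class AnsatzSpec:
    rotation_blocks: tuple = ("ry", "rz")
    entanglement_blocks: str = "cz"
    reps: int = 3
    entanglement: str = "full"

    def __post_init__(self):
        for g in self.rotation_blocks:
            if g not in ("ry", "rz"):
                raise ParameterError(f"unsupported rotation gate {g!r}")
        if self.entanglement_blocks != "cz":
            raise ParameterError("only cz entanglement blocks are supported")
        if self.reps < 0:
            raise ParameterError("reps must be >= 0")

    def n_parameters(self, n_qubits: int) -> int:
        return (self.reps + 1) * n_qubits * len(self.rotation_blocks)


def _apply_single(states: np.ndarray, gate: np.ndarray, qubit: int,
                  n: int) -> np.ndarray:
    """Apply a 2x2 gate on ``qubit`` to a batch of states (N, 2^n)."""
    batch = states.shape[0]
    reshaped = states.reshape(batch, -1, 2, 2**qubit)
    out = np.einsum("ab,nibj->niaj", gate, reshaped)
    return out.reshape(batch, -1)


def _ry(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    return np.array([[c, -s], [s, c]], dtype=complex)


def _rz(theta: float) -> np.ndarray:
    return np.array(
        [[np.exp(-0.5j * theta), 0], [0, np.exp(0.5j * theta)]], dtype=complex
    )


_GATES = {"ry": _ry, "rz": _rz}


@lru_cache(maxsize=32)
def _cz_diag(n: int, entanglement: str) -> np.ndarray:
    bits = _bits(n)
    sign = np.ones(2**n)
    for i, j in entangler_pairs(n, entanglement):
        sign *= np.where(bits[:, i] * bits[:, j] > 0, -1.0, 1.0)
    return sign


def apply_ansatz(
    states: np.ndarray, theta: np.ndarray, spec: AnsatzSpec, n: int
) -> np.ndarray:
    """Run the two-local circuit on a batch of states.

    Layer layout per repetition: one layer per rotation block (a gate on
    every qubit, qubit-major parameter order), then the cz entanglement
    layer; a final rotation layer closes the circuit.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    expected = spec.n_parameters(n)
    if len(theta) != expected:
        raise DimensionError(
            f"theta has {len(theta)} entries, ansatz needs {expected}"
        )
    single = states.ndim == 1
    # always copy: gates below write in place through reshaped views
    batch = np.array(states[None] if single else states, dtype=complex,
                     order="C", copy=True)
    cz = _cz_diag(n, spec.entanglement) if spec.reps > 0 else None
    k = 0
    for rep in range(spec.reps + 1):
        for gate_name in spec.rotation_blocks:
            layer = theta[k:k + n]
            k += n
            if gate_name == "rz":
                # a full rz layer is diagonal: one phase vector multiply
                diag = np.exp(1j * (_bits(n) @ layer - 0.5 * layer.sum()))
                batch = batch * diag
            else:  # ry, real 2x2 rotation applied in place per qubit
                for q in range(n):
                    view = batch.reshape(batch.shape[0], -1, 2, 2**q)
                    x0 = view[:, :, 0].copy()
                    x1 = view[:, :, 1]
                    c, s = np.cos(layer[q] / 2), np.sin(layer[q] / 2)
                    view[:, :, 0] = c * x0 - s * x1
                    view[:, :, 1] = s * x0 + c * x1
        if rep < spec.reps:
            batch = batch * cz
    return batch[0] if single else batch


@dataclass
class VQCModel:
    theta: np.ndarray
    bias: float
    feature_spec: FeatureMapSpec
    ansatz: AnsatzSpec
    classes: np.ndarray  # [class mapped to -1, class mapped to +1]
    shots: int = 0
    seed: int | None = None

    def __post_init__(self):
        if not -1.0 <= self.bias <= 1.0:
            raise ParameterError(f"bias must lie in [-1, 1], got {self.bias}")


def parity_probabilities(
    states: np.ndarray, n: int, shots: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """p(y = +1) (even bit parity) per state; exact or from sampled shots."""
    single = states.ndim == 1
    batch = states[None] if single else states
    probs = np.abs(batch) ** 2
    p_even = probs[:, _parity_mask(n)].sum(axis=1)
    p_even = np.clip(p_even, 0.0, 1.0)
    if shots:
        if rng is None:
            rng = np.random.default_rng()
        p_even = rng.binomial(shots, p_even) / shots
    return p_even[0] if single else p_even


def vqc_forward(
    x: np.ndarray,
    theta: np.ndarray,
    feature_spec: FeatureMapSpec,
    ansatz: AnsatzSpec,
    shots: int = 0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Empirical label distribution {+1: p, -1: 1 - p} for one input."""
    state = zz_feature_map(np.asarray(x, dtype=float), feature_spec)
    state = apply_ansatz(state, theta, ansatz, feature_spec.n_features)
    p_plus = float(parity_probabilities(state, feature_spec.n_features,
                                        shots=shots, rng=rng))
    return {1: p_plus, -1: 1.0 - p_plus}


def _forward_batch(
    states: np.ndarray, theta: np.ndarray, feature_spec: FeatureMapSpec,
    ansatz: AnsatzSpec,
) -> np.ndarray:
    out = apply_ansatz(states, theta, ansatz, feature_spec.n_features)
    return parity_probabilities(out, feature_spec.n_features)


def decide(p_plus: float, bias: float) -> int:
    """Label rule: y = +1 iff p(+1) > p(-1) - b."""
    return 1 if p_plus > (1.0 - bias) / 2.0 else -1


# ---------------------------------------------------------------------------
# SPSA


def spsa_minimize(
    objective,
    theta0: np.ndarray,
    c0: float = 4.0,
    maxiter: int = 40,
    seed: int | None = None,
    a: float | None = None,
    alpha: float = 0.602,
    gamma: float = 0.101,
) -> np.ndarray:
    """Simultaneous-perturbation stochastic approximation.

    Gains a_k = a / (k + 1 + A)^alpha and c_k = c0 / (k + 1)^gamma with
    A = 0.1 * maxiter; two objective evaluations per iteration with a
    seeded Rademacher perturbation. The default ``a`` makes the first step
    size 0.25.
    """
    if maxiter < 0:
        raise ParameterError(f"maxiter must be >= 0, got {maxiter}")
    theta = np.array(theta0, dtype=float).copy()
    if maxiter == 0:
        return theta
    rng = np.random.default_rng(seed)
    big_a = 0.1 * maxiter
    if a is None:
        a = 0.25 * (big_a + 1.0) ** alpha
    for k in range(maxiter):
        a_k = a / (k + 1 + big_a) ** alpha
        c_k = c0 / (k + 1) ** gamma
        delta = rng.choice([-1.0, 1.0], size=theta.shape)
        f_plus = objective(theta + c_k * delta)
        f_minus = objective(theta - c_k * delta)
        ghat = (f_plus - f_minus) / (2.0 * c_k) * delta  # 1/delta == delta
        theta -= a_k * ghat
    return theta


# ---------------------------------------------------------------------------
# VQC training


def vqc_fit(
    X: np.ndarray,
    y: np.ndarray,
    feature_spec: FeatureMapSpec,
    ansatz: AnsatzSpec = AnsatzSpec(),
    shots: int = 0,
    seed: int | None = None,
    c0: float = 4.0,
    maxiter: int = 40,
    spsa_a: float | None = None,
    theta0: np.ndarray | str = "zeros",
) -> VQCModel:
    """Train theta by SPSA on the cross-entropy of the parity readout, then
    pick the bias on a [-1, 1] grid (step 0.05) maximizing training
    balanced accuracy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ClassError(f"vqc_fit needs exactly 2 classes, got {classes!r}")
    signs = np.where(y == classes[1], 1, -1)
    rng = np.random.default_rng(seed)

    states = _feature_states(X, feature_spec)
    n = feature_spec.n_features

    def objective(theta: np.ndarray) -> float:
        p_plus = _forward_batch(states, theta, feature_spec, ansatz)
        if shots:
            p_plus = rng.binomial(shots, p_plus) / shots
        p_true = np.where(signs > 0, p_plus, 1.0 - p_plus)
        return float(-np.mean(np.log(np.clip(p_true, 1e-12, None))))

    n_params = ansatz.n_parameters(n)
    if isinstance(theta0, str):
        if theta0 == "zeros":
            theta0 = np.zeros(n_params)
        elif theta0 == "random":
            theta0 = rng.uniform(-np.pi, np.pi, size=n_params)
        else:
            raise ParameterError(f"unknown theta0 preset {theta0!r}")
    theta0 = np.asarray(theta0, dtype=float)
    theta = spsa_minimize(objective, theta0, c0=c0, maxiter=maxiter,
                          seed=None if seed is None else seed + 1, a=spsa_a)

    p_plus = _forward_batch(states, theta, feature_spec, ansatz)
    if shots:
        p_plus = rng.binomial(shots, p_plus) / shots
    best_bias, best_score = 0.0, -1.0
    for bias in np.arange(-1.0, 1.0 + 1e-9, 0.05):
        pred_signs = np.where(p_plus > (1.0 - bias) / 2.0, 1, -1)
        score = float(np.mean(
            [np.mean(pred_signs[signs == s] == s) for s in (-1, 1)]
        ))
        if score > best_score + 1e-12:
            best_bias, best_score = float(bias), score
    return VQCModel(
        theta=theta, bias=np.clip(best_bias, -1.0, 1.0),
        feature_spec=feature_spec, ansatz=ansatz, classes=classes,
        shots=shots, seed=seed,
    )


def vqc_predict(model: VQCModel, x: np.ndarray) -> np.ndarray:
    """Predict one sample or a batch with the trained circuit."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    batch = x[None] if single else x
    states = _feature_states(batch, model.feature_spec)
    p_plus = _forward_batch(states, model.theta, model.feature_spec,
                            model.ansatz)
    if model.shots:
        rng = np.random.default_rng(
            None if model.seed is None else model.seed + 2
        )
        p_plus = rng.binomial(model.shots, p_plus) / model.shots
    signs = np.array([decide(p, model.bias) for p in p_plus])
    pred = np.where(signs > 0, model.classes[1], model.classes[0])
    return pred[0] if single else pred


class QSVCClassifier:
    """sklearn-style wrapper for the quantum-kernel SVM."""

    def __init__(self, reps: int = 2, entanglement: str = "linear",
                 shots: int = 0, C: float = 1.0, seed: int | None = None):
        self.reps = reps
        self.entanglement = entanglement
        self.shots = shots
        self.C = C
        self.seed = seed

    def fit(self, X, y):
        spec = FeatureMapSpec(n_features=np.asarray(X).shape[1],
                              reps=self.reps, entanglement=self.entanglement)
        self.model_ = qsvc_fit(X, y, spec, shots=self.shots, C=self.C,
                               seed=self.seed)
        return self

    def predict(self, X):
        return np.atleast_1d(qsvc_predict(self.model_, X))


class VQCClassifier:
    """sklearn-style wrapper for the variational classifier."""

    def __init__(self, reps: int = 2, entanglement: str = "linear",
                 ansatz: AnsatzSpec = AnsatzSpec(), shots: int = 0,
                 seed: int | None = None, c0: float = 4.0, maxiter: int = 40):
        self.reps = reps
        self.entanglement = entanglement
        self.ansatz = ansatz
        self.shots = shots
        self.seed = seed
        self.c0 = c0
        self.maxiter = maxiter

    def fit(self, X, y):
        spec = FeatureMapSpec(n_features=np.asarray(X).shape[1],
                              reps=self.reps, entanglement=self.entanglement)
        self.model_ = vqc_fit(X, y, spec, ansatz=self.ansatz,
                              shots=self.shots, seed=self.seed,
                              c0=self.c0, maxiter=self.maxiter)
        return self

    def predict(self, X):
        return np.atleast_1d(vqc_predict(self.model_, X))
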