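import numpy as np
import pytest

from p300lab.exceptions import ClassError, DimensionError, ParameterError
from p300lab.quantum import (
    AnsatzSpec,
    FeatureMapSpec,
    apply_ansatz,
    decide,
    kernel_matrix,
    parity_probabilities,
    quantum_kernel,
    qsvc_fit,
    qsvc_predict,
    spsa_minimize,
    vqc_fit,
    vqc_forward,
    vqc_predict,
    zz_feature_map,
)

# ---------------------------------------------------------------------------
# independent dense-matrix oracle: builds each gate as an explicit 2^n x 2^n
# unitary via Kronecker products (qubit 0 = least-significant bit) and
# multiplies them out. Completely separate code path from the simulator.

I2 = np.eye(2, dtype=complex)
H1 = np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2)


def _kron_at(gate, qubit, n):
    ops = [I2] * n
    ops[qubit] = gate
    out = np.array([[1.0 + 0j]])
    for op in reversed(ops):  # qubit 0 is the LSB => rightmost kron factor
        out = np.kron(out, op)
    return out


def _controlled_phase(angle, q1, q2, n):
    dim = 2**n
    diag = np.ones(dim, dtype=complex)
    for z in range(dim):
        if (z >> q1) & 1 and (z >> q2) & 1:
            diag[z] = np.exp(1j * angle)
    return np.diag(diag)


def _cx(control, target, n):
    dim = 2**n
    mat = np.zeros((dim, dim), dtype=complex)
    for z in range(dim):
        z2 = z ^ (1 << target) if (z >> control) & 1 else z
        mat[z2, z] = 1.0
    return mat


def _phase_gate(angle, qubit, n):
    gate = np.diag([1.0, np.exp(1j * angle)]).astype(complex)
    return _kron_at(gate, qubit, n)


def oracle_feature_unitary(x, spec: FeatureMapSpec) -> np.ndarray:
    n = spec.n_features
    if spec.entanglement == "linear":
        pairs = [(i, i + 1) for i in range(n - 1)]
    else:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    u = np.eye(2**n, dtype=complex)
    for _ in range(spec.reps):
        layer = np.eye(2**n, dtype=complex)
        for q in range(n):
            layer = _kron_at(H1, q, n) @ layer
        for q in range(n):
            layer = _phase_gate(2.0 * x[q], q, n) @ layer
        for i, j in pairs:
            angle = 2.0 * (np.pi - x[i]) * (np.pi - x[j])
            layer = _cx(i, j, n) @ layer
            layer = _phase_gate(angle, j, n) @ layer
            layer = _cx(i, j, n) @ layer
        u = layer @ u
    return u


def _rot(gate, theta):
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    if gate == "ry":
        return np.array([[c, -s], [s, c]], dtype=complex)
    if gate == "rz":
        return np.diag([np.exp(-0.5j * theta), np.exp(0.5j * theta)])
    raise ValueError(gate)


def oracle_ansatz_unitary(theta, spec: AnsatzSpec, n) -> np.ndarray:
    if spec.entanglement == "linear":
        pairs = [(i, i + 1) for i in range(n - 1)]
    else:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    u = np.eye(2**n, dtype=complex)
    k = 0
    for rep in range(spec.reps + 1):
        for gate in spec.rotation_blocks:
            for q in range(n):
                u = _kron_at(_rot(gate, theta[k]), q, n) @ u
                k += 1
        if rep < spec.reps:
            for i, j in pairs:
                u = _controlled_phase(np.pi, i, j, n) @ u  # cz
    return u


# ---------------------------------------------------------------------------


class TestZZFeatureMap:
    def test_zero_input_uniform_magnitudes_single_rep(self):
        # after one repetition (Hadamards then diagonal phases) magnitudes
        # are exactly uniform; further Hadamard layers mix the pair phases
        # back into the magnitudes, so this only holds at reps=1
        for n in (1, 2, 3):
            state = zz_feature_map(np.zeros(n), FeatureMapSpec(n, reps=1))
            assert np.allclose(np.abs(state), 2 ** (-n / 2), atol=1e-10)

    def test_unit_norm(self):
        rng = np.random.default_rng(0)
        for n in (1, 2, 4):
            x = rng.uniform(-2, 2, n)
            state = zz_feature_map(x, FeatureMapSpec(n))
            assert np.linalg.norm(state) == pytest.approx(1.0, abs=1e-10)

    def test_matches_dense_oracle_2_qubits(self):
        spec = FeatureMapSpec(2, reps=2)
        x = np.array([0.5, 1.0])
        state = zz_feature_map(x, spec)
        ref = oracle_feature_unitary(x, spec)[:, 0]
        assert np.allclose(state, ref, atol=1e-10)

    @pytest.mark.parametrize("n,reps,entanglement", [
        (1, 1, "linear"), (2, 1, "linear"), (3, 2, "linear"),
        (3, 2, "full"), (4, 2, "linear"),
    ])
    def test_matches_dense_oracle_general(self, n, reps, entanglement):
        rng = np.random.default_rng(n * 10 + reps)
        x = rng.uniform(0, 2, n)
        spec = FeatureMapSpec(n, reps=reps, entanglement=entanglement)
        state = zz_feature_map(x, spec)
        ref = oracle_feature_unitary(x, spec)[:, 0]
        assert np.allclose(state, ref, atol=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            zz_feature_map(np.zeros(3), FeatureMapSpec(2))


class TestQuantumKernel:
    SPEC = FeatureMapSpec(3, reps=2)

    def test_self_kernel_is_one(self):
        x = np.array([0.3, -1.0, 2.0])
        assert quantum_kernel(x, x, self.SPEC) == pytest.approx(1.0, abs=1e-10)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(0, 2, 3), rng.uniform(0, 2, 3)
        assert quantum_kernel(x, y, self.SPEC) == quantum_kernel(y, x, self.SPEC)

    def test_shot_estimate_close_to_exact(self):
        # binomial error at R=1024: |estimate - exact| < 0.05 w.h.p.
        rng = np.random.default_rng(2)
        hits = 0
        n_pairs = 100
        for i in range(n_pairs):
            x, y = rng.uniform(0, 2, 3), rng.uniform(0, 2, 3)
            exact = quantum_kernel(x, y, self.SPEC)
            est = quantum_kernel(x, y, self.SPEC, shots=1024, seed=i)
            hits += abs(est - exact) < 0.05
        assert hits >= 0.95 * n_pairs

    def test_negative_shots_rejected(self):
        with pytest.raises(ParameterError):
            quantum_kernel(np.zeros(3), np.zeros(3), self.SPEC, shots=-1)

    def test_kernel_matrix_1x1(self):
        assert np.allclose(kernel_matrix(np.zeros((1, 3)), self.SPEC), [[1.0]])

    def test_kernel_matrix_psd_50_random_10dim(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 2, (50, 10))
        gram = kernel_matrix(X, FeatureMapSpec(10, reps=2))
        assert np.allclose(gram, gram.T)
        assert np.allclose(np.diag(gram), 1.0, atol=1e-10)
        assert np.linalg.eigvalsh(gram).min() >= -1e-8

    def test_duplicated_row_gives_identical_rows(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 2, (5, 3))
        X[3] = X[1]
        gram = kernel_matrix(X, self.SPEC)
        assert np.allclose(gram[1], gram[3], atol=1e-12)

    def test_shot_matrix_converges_with_R(self):
        # statistical halving: max-entry error at 4R ~ half that at R
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 2, (8, 3))
        exact = kernel_matrix(X, self.SPEC)
        errs = {}
        for shots in (256, 4096):
            err = []
            for seed in range(10):
                est = kernel_matrix(X, self.SPEC, shots=shots, seed=seed)
                err.append(np.abs(est - exact).max())
            errs[shots] = np.mean(err)
        assert errs[4096] < 0.7 * errs[256]


class TestQSVC:
    def test_separated_clusters_perfect_training(self):
        # seeded search for inputs whose exact kernel is ~orthogonal across
        # clusters and ~aligned within: scaling one feature by pi flips the
        # pair phases; verify with the kernel itself, then train.
        spec = FeatureMapSpec(2, reps=2)
        rng = np.random.default_rng(6)
        base_a, base_b = None, None
        for _ in range(500):
            a, b = rng.uniform(0, 2, 2), rng.uniform(0, 2, 2)
            if quantum_kernel(a, b, spec) < 0.1:
                base_a, base_b = a, b
                break
        assert base_a is not None
        X = np.vstack([
            base_a + rng.normal(0, 0.01, (6, 2)),
            base_b + rng.normal(0, 0.01, (6, 2)),
        ])
        y = np.array([0] * 6 + [1] * 6)
        within = quantum_kernel(X[0], X[1], spec)
        across = quantum_kernel(X[0], X[6], spec)
        assert within > 0.9 and across < 0.2
        model = qsvc_fit(X, y, spec)
        assert np.mean(qsvc_predict(model, X) == y) == 1.0

    def test_small_C_degenerates_to_bias_class(self):
        spec = FeatureMapSpec(2, reps=1)
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 2, (10, 2))
        y = np.array([0] * 7 + [1] * 3)
        model = qsvc_fit(X, y, spec, C=1e-6)
        pred = qsvc_predict(model, rng.uniform(0, 2, (20, 2)))
        assert np.all(pred == 0)  # majority class

    def test_shot_mode_converges_to_exact_predictions(self):
        spec = FeatureMapSpec(2, reps=2)
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0.5, 0.05, (6, 2)), rng.normal(1.8, 0.05, (6, 2))])
        y = np.array([0] * 6 + [1] * 6)
        exact_model = qsvc_fit(X, y, spec)
        shot_model = qsvc_fit(X, y, spec, shots=100_000, seed=1)
        assert np.array_equal(
            qsvc_predict(exact_model, X), qsvc_predict(shot_model, X)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ClassError):
            qsvc_fit(np.zeros((4, 2)), np.zeros(4), FeatureMapSpec(2))


class TestAnsatz:
    def test_matches_dense_oracle(self):
        for n, entanglement in [(2, "full"), (3, "full"), (3, "linear")]:
            spec = AnsatzSpec(reps=2, entanglement=entanglement)
            rng = np.random.default_rng(n)
            theta = rng.uniform(-np.pi, np.pi, spec.n_parameters(n))
            state0 = zz_feature_map(rng.uniform(0, 2, n), FeatureMapSpec(n))
            out = apply_ansatz(state0, theta, spec, n)
            ref = oracle_ansatz_unitary(theta, spec, n) @ state0
            assert np.allclose(out, ref, atol=1e-10)

    def test_norm_preserved(self):
        spec = AnsatzSpec()
        rng = np.random.default_rng(9)
        theta = rng.uniform(-np.pi, np.pi, spec.n_parameters(4))
        state = zz_feature_map(rng.uniform(0, 2, 4), FeatureMapSpec(4))
        out = apply_ansatz(state, theta, spec, 4)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-10)

    def test_theta_length_validated(self):
        with pytest.raises(DimensionError):
            apply_ansatz(np.zeros(4, dtype=complex), np.zeros(3),
                         AnsatzSpec(), 2)


class TestVQCForward:
    def test_zero_theta_reduces_to_feature_map_parity(self):
        # ry(0) = rz(0) = identity; cz only adds phases, which parity
        # probabilities ignore
        n = 3
        fspec = FeatureMapSpec(n)
        aspec = AnsatzSpec()
        x = np.zeros(n)
        dist = vqc_forward(x, np.zeros(aspec.n_parameters(n)), fspec, aspec)
        bare = zz_feature_map(x, fspec)
        p_plus = parity_probabilities(bare, n)
        assert dist[1] == pytest.approx(p_plus, abs=1e-10)

    def test_probabilities_sum_to_one(self):
        n = 3
        fspec, aspec = FeatureMapSpec(n), AnsatzSpec()
        rng = np.random.default_rng(10)
        dist = vqc_forward(rng.uniform(0, 2, n),
                           rng.uniform(-1, 1, aspec.n_parameters(n)),
                           fspec, aspec)
        assert dist[1] + dist[-1] == pytest.approx(1.0, abs=1e-10)

    def test_2_qubit_parity_matches_dense_oracle(self):
        n = 2
        fspec, aspec = FeatureMapSpec(n), AnsatzSpec(reps=2)
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 2, n)
        theta = rng.uniform(-np.pi, np.pi, aspec.n_parameters(n))
        dist = vqc_forward(x, theta, fspec, aspec)
        u = oracle_ansatz_unitary(theta, aspec, n) @ oracle_feature_unitary(
            x, fspec
        )
        amps = u[:, 0]
        # even parity of bits(z) => label +1
        p_plus_ref = sum(
            abs(a) ** 2 for z, a in enumerate(amps) if bin(z).count("1") % 2 == 0
        )
        assert dist[1] == pytest.approx(p_plus_ref, abs=1e-10)

    def test_decision_rule_with_bias(self):
        # y=+1 iff p(+1) > p(-1) - b
        assert decide(0.45, 0.2) == 1   # 0.45 > 0.55 - 0.2
        assert decide(0.45, 0.0) == -1
        assert decide(0.5, 0.0) == -1   # strict inequality


class TestSPSA:
    def test_maxiter_zero_returns_theta0(self):
        theta0 = np.array([1.0, 2.0])
        out = spsa_minimize(lambda t: float(t @ t), theta0, maxiter=0, seed=0)
        assert np.array_equal(out, theta0)

    def test_negative_maxiter_rejected(self):
        with pytest.raises(ParameterError):
            spsa_minimize(lambda t: 0.0, np.zeros(2), maxiter=-1)

    def test_seed_determinism(self):
        f = lambda t: float(np.sum((t - 1.0) ** 2))
        a = spsa_minimize(f, np.zeros(4), maxiter=50, seed=3)
        b = spsa_minimize(f, np.zeros(4), maxiter=50, seed=3)
        assert np.array_equal(a, b)

    def test_quadratic_recovery(self):
        star = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 1000)
            theta0 = star + rng.uniform(-2, 2, 5)
            f = lambda t: float(np.sum((t - star) ** 2))
            theta = spsa_minimize(f, theta0, maxiter=500, seed=seed)
            hits += np.linalg.norm(theta - star) < 0.1
        assert hits >= 0.9 * n_seeds


class TestVQCFit:
    def test_labels_from_model_family_are_learnable(self):
        # labels generated by thresholding the untrained circuit's parity
        # probability: the family contains the truth, training must fit it
        n = 2
        fspec, aspec = FeatureMapSpec(n), AnsatzSpec(reps=1)
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 2, (24, n))
        theta_untrained = np.zeros(aspec.n_parameters(n))
        p = np.array(
            [vqc_forward(x, theta_untrained, fspec, aspec)[1] for x in X]
        )
        y = (p > np.median(p)).astype(int)
        model = vqc_fit(X, y, fspec, aspec, seed=5, maxiter=40)
        pred = vqc_predict(model, X)
        assert np.mean(pred == y) >= 0.95

    def test_bias_in_range(self):
        n = 2
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 2, (12, n))
        y = np.array([0, 1] * 6)
        model = vqc_fit(X, y, FeatureMapSpec(n), AnsatzSpec(reps=1),
                        seed=0, maxiter=10)
        assert -1.0 <= model.bias <= 1.0

    def test_label_shuffled_no_generalization_signal(self):
        n = 2
        fspec, aspec = FeatureMapSpec(n), AnsatzSpec(reps=1)
        scores = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 2, (20, n))
            y = rng.permutation([0, 1] * 10)
            model = vqc_fit(X, y, fspec, aspec, seed=seed, maxiter=20)
            from p300lab.evaluate import balanced_accuracy

            scores.append(balanced_accuracy(y, vqc_predict(model, X)))
        assert all(0.4 <= s <= 0.85 for s in scores)

    def test_single_class_rejected(self):
        with pytest.raises(ClassError):
            vqc_fit(np.zeros((4, 2)), np.zeros(4), FeatureMapSpec(2))
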