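import numpy as np
import pytest

from oracles import qp_dual_solve, random_svm_problem
from svmswarm import (
    FeatureMatrix,
    KernelSpec,
    decision_value,
    decision_values,
    gram_matrix,
    kernel_eval,
    model_from_json,
    model_to_json,
    svm_predict,
    svm_train,
)
from svmswarm.data import (
    DimensionMismatch,
    NonPositivePhi,
    SingleClassInput,
)
from svmswarm.svm_core import ALPHA_EPS, svm_train_from_kernel


class TestKernels:
    def test_gaussian_at_zero_distance_is_one(self, rng):
        k = KernelSpec(family="gaussian", phi=2.3)
        x = rng.normal(size=5)
        assert kernel_eval(k, x, x) == pytest.approx(1.0)

    def test_gaussian_unit_distance_unit_width(self):
        k = KernelSpec(family="gaussian", phi=1.0)
        assert kernel_eval(k, np.array([0.0]), np.array([1.0])) == pytest.approx(
            np.exp(-1.0)
        )

    def test_polynomial_hand_example(self):
        # a=1, b=2, x.y=1 -> (1+1)^2 = 4
        k = KernelSpec(family="polynomial", a=1.0, b=2)
        assert kernel_eval(k, np.array([1.0, 0.0]), np.array([1.0, 5.0])) == 4.0

    def test_symmetry(self, rng):
        x, y = rng.normal(size=4), rng.normal(size=4)
        for k in (KernelSpec("gaussian", phi=0.7), KernelSpec("polynomial"),
                  KernelSpec("linear")):
            assert kernel_eval(k, x, y) == pytest.approx(kernel_eval(k, y, x))

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionMismatch):
            kernel_eval(KernelSpec("linear"), np.ones(2), np.ones(3))

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(NonPositivePhi):
            KernelSpec(family="gaussian", phi=0.0)

    def test_gamma_phi_correspondence(self):
        k = KernelSpec.gaussian_from_gamma(4.0)
        assert k.phi == pytest.approx(0.5)
        assert k.gamma == pytest.approx(4.0)


class TestGram:
    def test_gaussian_diagonal_is_ones(self, rng):
        K = gram_matrix(KernelSpec("gaussian", phi=1.3), rng.normal(size=(8, 3)))
        assert np.diag(K) == pytest.approx(np.ones(8))

    def test_gaussian_gram_is_psd(self, rng):
        K = gram_matrix(KernelSpec("gaussian", phi=1.0), rng.normal(size=(10, 4)))
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_linear_gram_of_one_hot_rows_is_identity(self):
        K = gram_matrix(KernelSpec("linear"), np.eye(5))
        assert K == pytest.approx(np.eye(5))


class TestTraining:
    def test_two_point_problem_solved_exactly(self, toy_two_points):
        # dual by hand: alpha1 = alpha2 = 0.5, b = 0, f(x) = x
        m = svm_train(toy_two_points, C=10.0, kernel=KernelSpec("linear"))
        assert m.alphas == pytest.approx([0.5, 0.5], abs=1e-6)
        assert m.bias == pytest.approx(0.0, abs=1e-6)
        assert decision_value(m, np.array([0.0])) == pytest.approx(0.0, abs=1e-6)
        assert decision_value(m, np.array([2.0])) == pytest.approx(2.0, abs=1e-4)

    def test_two_point_predictions(self, toy_two_points):
        m = svm_train(toy_two_points, C=10.0, kernel=KernelSpec("linear"))
        assert np.array_equal(
            svm_predict(m, np.array([[-2.0], [2.0]])), [-1, 1]
        )

    def test_xor_with_gaussian_kernel(self):
        X = FeatureMatrix(
            values=np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]]),
            labels=np.array([-1, -1, 1, 1]),
        )
        m = svm_train(X, C=10.0, kernel=KernelSpec("gaussian", phi=1.0))
        assert np.array_equal(svm_predict(m, X), X.labels)

    def test_separable_blobs_perfect_training_accuracy(self, blobs_far):
        m = svm_train(blobs_far, C=10.0, kernel=KernelSpec("linear"))
        assert np.array_equal(svm_predict(m, blobs_far), blobs_far.labels)

    def test_single_class_rejected(self, rng):
        X = FeatureMatrix(values=rng.normal(size=(5, 2)), labels=np.ones(5, int))
        with pytest.raises(SingleClassInput):
            svm_train(X, C=1.0, kernel=KernelSpec("linear"))

    def test_dual_feasibility_random_problems(self, rng):
        for _ in range(10):
            _, y, K = random_svm_problem(rng)
            C = 10.0 ** rng.uniform(-1, 2)
            alpha, _, _, _ = svm_train_from_kernel(K, y, C)
            assert (alpha >= -1e-12).all() and (alpha <= C + 1e-12).all()
            assert alpha @ y == pytest.approx(0.0, abs=1e-6)

    def test_dual_objective_matches_qp_oracle(self, rng):
        for _ in range(10):
            _, y, K = random_svm_problem(rng)
            _, _, _, obj = svm_train_from_kernel(K, y, 10.0)
            _, oracle_obj = qp_dual_solve(K, y, 10.0)
            assert obj == pytest.approx(oracle_obj, rel=1e-4, abs=1e-6)

    def test_kkt_conditions(self, rng):
        for _ in range(6):
            X, y, K = random_svm_problem(rng)
            C = 5.0
            alpha, bias, conv, _ = svm_train_from_kernel(K, y, C)
            assert conv
            yf = y * (K @ (alpha * y) + bias)
            at_zero = alpha <= ALPHA_EPS
            at_C = alpha >= C - ALPHA_EPS
            free = ~at_zero & ~at_C
            assert (yf[at_zero] >= 1 - 1e-2).all()
            assert np.abs(yf[free] - 1).max(initial=0.0) <= 1e-2
            assert (yf[at_C] <= 1 + 1e-2).all()

    def test_free_support_vectors_sit_on_margin(self, rng):
        X, y, K = random_svm_problem(rng)
        C = 5.0
        alpha, bias, _, _ = svm_train_from_kernel(K, y, C)
        free = (alpha > ALPHA_EPS) & (alpha < C - ALPHA_EPS)
        if free.any():
            yf = y * (K @ (alpha * y) + bias)
            assert yf[free] == pytest.approx(np.ones(free.sum()), abs=1e-2)

    def test_rotation_invariance_of_gaussian_decision(self, rng):
        X = FeatureMatrix(
            values=rng.normal(size=(20, 3)),
            labels=np.resize([1, -1], 20),
        )
        k = KernelSpec("gaussian", phi=1.5)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        m1 = svm_train(X, 3.0, k)
        m2 = svm_train(X.with_values(X.values @ Q), 3.0, k)
        probe = rng.normal(size=(7, 3))
        assert decision_values(m1, probe) == pytest.approx(
            decision_values(m2, probe @ Q), abs=1e-6
        )

    def test_prediction_invariant_to_row_permutation(self, rng):
        X = FeatureMatrix(
            values=rng.normal(size=(24, 3)), labels=np.resize([1, -1], 24)
        )
        perm = rng.permutation(24)
        k = KernelSpec("gaussian", phi=1.0)
        m1 = svm_train(X, 2.0, k)
        m2 = svm_train(X.take(perm), 2.0, k)
        probe = rng.normal(size=(10, 3))
        assert np.array_equal(svm_predict(m1, probe), svm_predict(m2, probe))


def test_json_roundtrip_is_bit_stable(rng, blobs_far):
    m = svm_train(blobs_far, C=3.0, kernel=KernelSpec("gaussian", phi=2.0))
    m2 = model_from_json(model_to_json(m))
    probe = rng.normal(size=(15, blobs_far.d))
    f1, f2 = decision_values(m, probe), decision_values(m2, probe)
    assert np.array_equal(f1, f2)  # bitwise
    assert model_to_json(m2) == model_to_json(m)
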