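import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVC

from svmrfe import KernelSpec, LabeledSet, decision_value, fit_psvm, standardize
from svmrfe.psvm import PSVMResults, ProbabilisticSVM

from conftest import random_classification


class TestStandardize:
    def test_hand_column(self):
        Z, scaler = standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Z.ravel(), [-1.0, 0.0, 1.0])
        assert scaler.scale[0] == pytest.approx(1.0)

    def test_idempotent_on_standardized_data(self, rng):
        X = rng.normal(size=(50, 3))
        Z, _ = standardize(X)
        Z2, _ = standardize(Z)
        np.testing.assert_allclose(Z, Z2, atol=1e-12)

    def test_constant_column_maps_to_zeros_with_unit_scale(self):
        Z, scaler = standardize(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        np.testing.assert_allclose(Z[:, 0], 0.0)
        assert scaler.scale[0] == 1.0

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.array([[1.0], [np.nan]]))


class TestFitPSVM:
    def test_separable_pair_signs(self, linear):
        data = LabeledSet.from_labels(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]))
        res = fit_psvm(data, kernel=linear, C=1e3, standardize=False)
        d = res.decision_function(data.X)
        assert np.sign(d[0]) == -1 and np.sign(d[1]) == 1

    def test_midpoint_of_separable_pair_is_zero(self, linear):
        data = LabeledSet.from_labels(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]))
        res = fit_psvm(data, kernel=linear, C=1e3, standardize=False)
        assert decision_value(res, np.array([0.0])) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_all_certain_matches_standard_svm(self, seed):
        """With pi in {0,1} the probabilistic SVM is exactly a C-SVM."""
        rng = np.random.default_rng(seed)
        data = random_classification(seed)
        C = float(rng.choice([0.5, 1.0, 10.0, 100.0]))
        sigma = float(rng.choice([0.5, 1.0, 2.0]))
        res = fit_psvm(data, KernelSpec("gaussian", sigma), C=C, Ctilde=7.7, standardize=False)
        ref = SVC(C=C, gamma=1.0 / sigma, tol=1e-8).fit(data.X, data.y)
        np.testing.assert_allclose(
            res.decision_function(data.X), ref.decision_function(data.X), atol=1e-4
        )

    def test_uncertain_midpoint_sample_scores_zero(self, linear):
        """A pi=0.5 sample at the symmetry center of balanced classes sits on
        the decision boundary."""
        X = np.array([[-2.0], [-1.0], [0.0], [1.0], [2.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0, 1.0])
        pi = np.array([0.0, 0.0, 0.5, 1.0, 1.0])
        data = LabeledSet(X=X, y=y, pi=pi)
        res = fit_psvm(data, kernel=linear, C=1.0, Ctilde=1.0, standardize=False)
        assert decision_value(res, np.array([0.0])) == pytest.approx(0.0, abs=1e-6)

    def test_dual_matches_slsqp_oracle(self, linear):
        """SMO solution agrees with an independent QP solve of the same dual."""
        X = np.array([[-2.0], [-1.0], [0.2], [1.0], [2.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0, 1.0])
        data = LabeledSet.from_labels(X, y)
        C = 2.0
        res = fit_psvm(data, kernel=linear, C=C, standardize=False)
        K = X @ X.T
        Q = np.outer(y, y) * K

        def neg_dual(a):
            return 0.5 * a @ Q @ a - a.sum()

        cons = {"type": "eq", "fun": lambda a: a @ y}
        sol = minimize(neg_dual, np.full(5, 0.1), method="SLSQP",
                       bounds=[(0, C)] * 5, constraints=cons,
                       options={"ftol": 1e-12, "maxiter": 500})
        w_oracle = (sol.x * y) @ X
        w_mine = res.linear_weights()
        np.testing.assert_allclose(w_mine, w_oracle, atol=1e-4)

    def test_label_swap_antisymmetry(self):
        data = random_classification(3)
        pi = data.pi.copy()
        pi[0] = 0.3  # make one sample uncertain
        d1 = LabeledSet(X=data.X, y=data.y, pi=pi)
        y2 = -data.y
        y2[0] = 1.0 if pi[0] < 0.5 else -1.0
        d2 = LabeledSet(X=data.X, y=np.where(1 - pi >= 0.5, 1.0, -1.0), pi=1 - pi)
        spec = KernelSpec("gaussian", 1.5)
        f1 = fit_psvm(d1, spec, C=2.0, Ctilde=3.0, standardize=False).decision_function(data.X)
        f2 = fit_psvm(d2, spec, C=2.0, Ctilde=3.0, standardize=False).decision_function(data.X)
        np.testing.assert_allclose(f1, -f2, atol=1e-6)

    def test_training_order_invariance(self):
        data = random_classification(5)
        perm = np.random.default_rng(1).permutation(len(data.y))
        shuffled = LabeledSet(X=data.X[perm], y=data.y[perm], pi=data.pi[perm])
        spec = KernelSpec("gaussian", 1.0)
        f1 = fit_psvm(data, spec, C=5.0, standardize=False).decision_function(data.X)
        f2 = fit_psvm(shuffled, spec, C=5.0, standardize=False).decision_function(data.X)
        np.testing.assert_allclose(f1, f2, atol=1e-6)

    def test_single_class_rejected(self, linear):
        data = LabeledSet.from_labels(np.array([[0.0], [1.0]]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            fit_psvm(data, kernel=linear)


class TestDecisionValue:
    def test_empty_expansion_returns_offset(self, toy_labeled, gaussian):
        res = fit_psvm(toy_labeled, gaussian, C=1.0, standardize=False)
        res.alpha = np.empty(0)
        res.y_support = np.empty(0)
        assert res.decision_function(toy_labeled.X[:1])[0] == pytest.approx(res.b)

    def test_hand_built_three_point_model(self):
        """f(x) = sum rho_i k(x_i, x) + b summed by hand."""
        spec = KernelSpec("gaussian", 1.0)
        sup = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        rho = np.array([0.5, -0.25, 0.75])
        model = ProbabilisticSVM(
            LabeledSet.from_labels(sup, np.array([1.0, -1.0, 1.0])), kernel=spec
        )
        res = PSVMResults(model=model, alpha=np.abs(rho), y_support=np.sign(rho),
                          support_X=sup, b=0.1,
                          scaler=__import__("svmrfe").Standardizer(np.zeros(2), np.ones(2)),
                          n_iter=0)
        x = np.array([0.5, 0.5])
        expected = 0.1 + sum(
            r * np.exp(-np.sum((s - x) ** 2)) for r, s in zip(rho, sup)
        )
        assert res.decision_function(x[None], standardized=True)[0] == pytest.approx(expected)

    def test_dimension_mismatch_raises(self, toy_labeled, gaussian):
        res = fit_psvm(toy_labeled, gaussian)
        with pytest.raises(ValueError):
            res.decision_function(np.zeros((1, 7)))

    def test_decision_gradient_matches_finite_difference(self, toy_labeled):
        spec = KernelSpec("gaussian", 2.5)
        res = fit_psvm(toy_labeled, spec, C=5.0, standardize=False)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=toy_labeled.X.shape[1])
            g = res.decision_gradient(x)
            h = 1e-6
            for a in range(len(x)):
                e = np.zeros_like(x)
                e[a] = h
                fd = (res.decision_function((x + e)[None], standardized=True)
                      - res.decision_function((x - e)[None], standardized=True))[0] / (2 * h)
                assert g[a] == pytest.approx(fd, rel=1e-4, abs=1e-10)
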