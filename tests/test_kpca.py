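import numpy as np
import pytest
from sklearn.decomposition import PCA

from svmrfe import (
    KernelSpec,
    LabeledSet,
    MaxGrowthRFE,
    angle,
    coordinate_growth_field,
    decision_function_growth_field,
    field_angles,
    fit_psvm,
    growth_direction,
    kpca_fit,
    project_point,
)

from conftest import random_classification


def _planted(seed, n=60, p=3, noise=0.3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.sign(X[:, 0] + noise * rng.normal(size=n))
    y[y == 0] = 1
    return LabeledSet.from_labels(X, y, names=[f"v{j+1}" for j in range(p)])


class TestKPCAFit:
    def test_linear_kernel_matches_classical_pca(self, rng, linear):
        X = rng.normal(size=(10, 4))
        emb = kpca_fit(X, kernel=linear, r=2)
        ref = PCA(n_components=2).fit_transform(X - X.mean(axis=0))
        for k in range(2):
            s = np.sign(emb.scores[:, k] @ ref[:, k])
            np.testing.assert_allclose(emb.scores[:, k], s * ref[:, k], atol=1e-8)

    def test_duplicated_rows_duplicate_scores(self, gaussian, rng):
        X = rng.normal(size=(6, 3))
        X2 = np.vstack([X, X[0]])
        emb = kpca_fit(X2, kernel=gaussian, r=2)
        np.testing.assert_allclose(emb.scores[0], emb.scores[-1], atol=1e-10)

    def test_collinear_data_second_eigenvalue_vanishes(self, linear):
        t = np.linspace(-1, 1, 8)
        X = np.column_stack([t, 2 * t])
        emb = kpca_fit(X, kernel=linear, r=2)
        assert emb.eigenvalues[-1] <= emb.eigenvalues[0] * 1e-8 or emb.r == 1

    def test_training_scores_reproduced_by_projection(self, gaussian, rng):
        X = rng.normal(size=(9, 3))
        emb = kpca_fit(X, kernel=gaussian, r=2)
        for i in range(9):
            np.testing.assert_allclose(project_point(emb, X[i]), emb.scores[i], atol=1e-8)


class TestProjectPoint:
    def test_linear_kernel_projects_like_pca(self, rng, linear):
        X = rng.normal(size=(12, 3))
        emb = kpca_fit(X, kernel=linear, r=2)
        pca = PCA(n_components=2).fit(X - X.mean(axis=0))
        x = rng.normal(size=3)
        mine = project_point(emb, x)
        ref = pca.transform((x - X.mean(axis=0))[None])[0]
        for k in range(2):
            s = np.sign(emb.scores[:, k] @ pca.transform(X - X.mean(axis=0))[:, k])
            assert mine[k] == pytest.approx(s * ref[k], abs=1e-8)

    def test_far_point_tends_to_centered_zero_projection(self, gaussian, rng):
        X = rng.normal(size=(8, 2))
        emb = kpca_fit(X, kernel=gaussian, r=2)
        far = project_point(emb, np.array([100.0, 100.0]))
        expected = (np.zeros(8) - emb.row_mean) @ emb.projector
        np.testing.assert_allclose(far, expected, atol=1e-10)

    def test_dimension_mismatch(self, gaussian, rng):
        emb = kpca_fit(rng.normal(size=(5, 2)), kernel=gaussian)
        with pytest.raises(ValueError):
            project_point(emb, np.zeros(3))


class TestGrowthDirection:
    def test_zero_partials_zero_vector(self, gaussian, rng):
        emb = kpca_fit(rng.normal(size=(6, 3)), kernel=gaussian)
        np.testing.assert_allclose(growth_direction(emb, np.zeros(3), np.zeros(3)), 0.0)

    def test_linear_kernel_coordinate_matches_pca_loading(self, rng, linear):
        X = rng.normal(size=(15, 4))
        emb = kpca_fit(X, kernel=linear, r=2)
        # f = coordinate a: gradient e_a, metric identity; projection of e_a
        # onto the PCA axes equals the a-th loading row (up to the fit's signs)
        pca = PCA(n_components=2).fit(X - X.mean(axis=0))
        for a in range(4):
            partials = np.eye(4)[a]
            d = growth_direction(emb, partials, X[0])
            ref = pca.components_[:, a]
            for k in range(2):
                s = np.sign(emb.scores[:, k] @ pca.transform(X - X.mean(axis=0))[:, k])
                assert d[k] == pytest.approx(s * ref[k], abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_master_oracle_tangent_equals_finite_difference(self, seed):
        """The projected tangent of the gradient curve equals a central finite
        difference of the point projection along the input-space velocity."""
        rng = np.random.default_rng(seed)
        spec = KernelSpec("gaussian", 2.0)
        X = rng.normal(size=(10, 3))
        emb = kpca_fit(X, kernel=spec, r=2)
        x0 = rng.normal(scale=0.5, size=3)
        partials = rng.normal(size=3)
        tangent = growth_direction(emb, partials, x0)
        dxdt = (spec.sigma / 2.0) * partials
        h = 1e-5
        fd = (project_point(emb, x0 + h * dxdt) - project_point(emb, x0 - h * dxdt)) / (2 * h)
        np.testing.assert_allclose(tangent, fd, rtol=1e-3, atol=1e-8)


class TestCoordinateFields:
    def test_identical_columns_identical_fields(self, gaussian, rng):
        x = rng.normal(size=(8, 1))
        X = np.hstack([x, x, rng.normal(size=(8, 1))])
        emb = kpca_fit(X, kernel=gaussian, r=2)
        f0 = coordinate_growth_field(emb, 0)
        f1 = coordinate_growth_field(emb, 1)
        np.testing.assert_allclose(f0.vectors, f1.vectors, atol=1e-10)

    def test_negated_column_negates_field(self, gaussian, rng):
        x = rng.normal(size=(8, 1))
        X = np.hstack([x, -x, rng.normal(size=(8, 1))])
        emb = kpca_fit(X, kernel=gaussian, r=2)
        f0 = coordinate_growth_field(emb, 0)
        f1 = coordinate_growth_field(emb, 1)
        np.testing.assert_allclose(f0.vectors, -f1.vectors, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_independent_noise_angles_scatter_about_right_angle(self, seed):
        """A noise variable's arrows bear no consistent relation to the
        decision-function reference (mean angle near pi/2), while an
        informative variable's arrows align or anti-align with it."""
        rng = np.random.default_rng(seed)
        n = 60
        x1 = rng.normal(size=n)
        y = np.sign(x1 + 0.2 * rng.normal(size=n))
        y[y == 0] = 1
        X = np.column_stack([x1, 0.9 * x1 + 0.1 * rng.normal(size=n), rng.normal(size=n)])
        data = LabeledSet.from_labels(X, y)
        spec = KernelSpec("gaussian", 6.0)
        res = fit_psvm(data, spec, C=10.0, standardize=False)
        emb = kpca_fit(X, kernel=spec, r=2)
        ref = decision_function_growth_field(emb, res)
        mean = lambda j: np.nanmean(field_angles(coordinate_growth_field(emb, j), ref))
        half_pi = np.pi / 2
        assert abs(mean(2) - half_pi) < abs(mean(0) - half_pi)


class TestDecisionFunctionField:
    def test_zero_rho_zero_field(self, gaussian, rng):
        data = random_classification(0, n=10, p=3)
        res = fit_psvm(data, gaussian, standardize=False)
        res.alpha = np.zeros_like(res.alpha)
        emb = kpca_fit(data.X, kernel=gaussian, r=2)
        f = decision_function_growth_field(emb, res)
        np.testing.assert_allclose(f.vectors, 0.0, atol=1e-12)

    def test_kernel_mismatch_rejected(self, rng):
        data = random_classification(0, n=10, p=3)
        res = fit_psvm(data, KernelSpec("gaussian", 1.0), standardize=False)
        emb = kpca_fit(data.X, kernel=KernelSpec("gaussian", 2.0), r=2)
        with pytest.raises(ValueError):
            decision_function_growth_field(emb, res)

    def test_field_points_between_classes_along_pc1(self):
        """On a separable two-cluster toy the decision-function arrows run
        from one class toward the other along the leading axis."""
        rng = np.random.default_rng(2)
        n = 30
        X = np.vstack([
            rng.normal(loc=(-2.0, 0.0), scale=0.4, size=(n // 2, 2)),
            rng.normal(loc=(2.0, 0.0), scale=0.4, size=(n // 2, 2)),
        ])
        y = np.concatenate([-np.ones(n // 2), np.ones(n // 2)])
        data = LabeledSet.from_labels(X, y)
        spec = KernelSpec("gaussian", 8.0)
        res = fit_psvm(data, spec, C=10.0, standardize=False)
        emb = kpca_fit(X, kernel=spec, r=2)
        f = decision_function_growth_field(emb, res)
        # PC1 separates the clusters; arrows should share the PC1 sign that
        # leads from the -1 cluster toward the +1 cluster
        pc1_dir = np.sign(emb.scores[y > 0, 0].mean() - emb.scores[y < 0, 0].mean())
        assert np.mean(np.sign(f.vectors[:, 0]) == pc1_dir) > 0.9


class TestAngle:
    def test_parallel_zero(self):
        assert angle(np.array([1.0, 2.0]), np.array([2.0, 4.0])) == pytest.approx(0.0, abs=1e-6)

    def test_antiparallel_pi(self):
        assert angle(np.array([1.0, 0.0]), np.array([-3.0, 0.0])) == pytest.approx(np.pi)

    def test_orthogonal_half_pi(self):
        assert angle(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(np.pi / 2)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angle(np.zeros(2), np.array([1.0, 0.0]))

    def test_scale_invariance_of_field_angles(self, gaussian, rng):
        X = rng.normal(size=(10, 3))
        emb = kpca_fit(X, kernel=gaussian, r=2)
        f = coordinate_growth_field(emb, 0)
        ref = coordinate_growth_field(emb, 1)
        a1 = field_angles(f, ref)
        scaled = type(f)(label=f.label, vectors=5.0 * f.vectors)
        np.testing.assert_allclose(a1, field_angles(scaled, ref), atol=1e-12)


class TestMaxGrowthRFE:
    def test_noise_removed_first_in_planted_fixture(self):
        """With one informative and two noise variables the first elimination
        hits a noise variable (prediction variant)."""
        wins = 0
        for seed in range(20):
            data = _planted(seed)
            res = MaxGrowthRFE(data, kernel=KernelSpec("gaussian", 2.0), C=10.0,
                               variant="prediction").fit()
            wins += res.ranks["v1"] <= 2
        assert wins >= 18

    def test_negated_copy_has_supplementary_angle(self):
        rng = np.random.default_rng(4)
        n = 50
        x1 = rng.normal(size=n)
        y = np.sign(x1 + 0.2 * rng.normal(size=n))
        y[y == 0] = 1
        X = np.column_stack([x1, -x1, rng.normal(size=n)])
        data = LabeledSet.from_labels(X, y, names=["up", "down", "noise"])
        ranker = MaxGrowthRFE(data, kernel=KernelSpec("gaussian", 4.0), C=10.0,
                              variant="function")
        model = ranker._refit(ranker.data)
        angles = ranker._mean_angles(model, ranker.data)
        assert angles[0] + angles[1] == pytest.approx(np.pi, abs=1e-6)

    def test_single_variable_rank_one(self):
        data = random_classification(0, n=12, p=1)
        res = MaxGrowthRFE(data, kernel=KernelSpec("gaussian", 2.0)).fit()
        assert list(res.ranks.values()) == [1]

    def test_variants_concordant_on_strong_signal(self):
        """Prediction and function variants make the same relevance call on a
        strongly separable fixture: neither eliminates the planted signal
        first.  (Deeper in the elimination, once noise variables no longer
        outnumber signals, the closest-to-median rule stops discriminating by
        construction, so concordance is assessed at the first cut.)"""
        keep_p = keep_f = 0
        for seed in range(20):
            data = _planted(seed, n=80, noise=0.05)
            spec = KernelSpec("gaussian", 4.0)
            rp = MaxGrowthRFE(data, kernel=spec, C=10.0, variant="prediction").fit()
            rf = MaxGrowthRFE(data, kernel=spec, C=10.0, variant="function").fit()
            keep_p += rp.ranks["v1"] <= 2
            keep_f += rf.ranks["v1"] <= 2
        assert keep_p >= 16
        assert keep_f >= 16

    def test_column_permutation_permutes_ranks_up_to_final_tie(self):
        """Reordering columns permutes the elimination order identically,
        except for the final pair where the median rule always ties and the
        lowest-index rule (intentionally position-dependent) decides."""
        data = _planted(1)
        spec = KernelSpec("gaussian", 2.0)
        r1 = MaxGrowthRFE(data, kernel=spec, C=10.0, variant="prediction").fit()
        perm = [2, 0, 1]
        data2 = LabeledSet(X=data.X[:, perm], y=data.y, pi=data.pi,
                           names=[data.names[j] for j in perm])
        r2 = MaxGrowthRFE(data2, kernel=spec, C=10.0, variant="prediction").fit()
        top2 = lambda r: {k for k, v in r.ranks.items() if v <= 2}
        assert top2(r1) == top2(r2)
        for v in data.names:
            if r1.ranks[v] > 2:
                assert r1.ranks[v] == r2.ranks[v]
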