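import numpy as np
import numpy.testing as npt
import pytest

from dynml import (
    IntegratorConfig,
    TrainingBatch,
    accuracy,
    apply_scaler,
    embed_dataset,
    evaluate,
    fit_classifier_readout,
    fit_readout,
    fit_scaler,
    invert_scaler,
    make_projection,
    predict,
    predict_labels,
    project_input,
    sample_lorenz_params,
)
from dynml.embedding_readout import ProjectionMatrix, ReadoutMatrix


class TestProjection:
    def test_shape_contract(self):
        proj = make_projection(4, 5, np.random.default_rng(0))
        assert proj.R.shape == (15, 4)

    def test_seed_determinism(self):
        a = make_projection(3, 2, np.random.default_rng(1)).R
        b = make_projection(3, 2, np.random.default_rng(1)).R
        npt.assert_array_equal(a, b)

    def test_zero_input_maps_to_zero(self):
        proj = make_projection(6, 3, np.random.default_rng(2))
        npt.assert_array_equal(project_input(np.zeros(6), proj), 0.0)

    def test_linearity_against_matmul(self):
        rng = np.random.default_rng(3)
        proj = make_projection(4, 2, rng)
        u = rng.normal(size=4)
        npt.assert_allclose(project_input(2.0 * u, proj),
                            2.0 * (proj.R @ u), rtol=0, atol=1e-12)

    def test_identity_like_projection(self):
        proj = ProjectionMatrix(R=np.eye(3), scale=1.0)
        npt.assert_array_equal(project_input(np.array([1.0, 2.0, 3.0]), proj),
                               [1.0, 2.0, 3.0])

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            make_projection(0, 5, np.random.default_rng(0))


class TestScaler:
    def test_two_point_column(self):
        sc = fit_scaler(np.array([[1.0], [3.0]]))
        npt.assert_allclose(apply_scaler(sc, np.array([[1.0], [3.0]])),
                            [[-1.0], [1.0]], rtol=0, atol=1e-12)

    def test_constant_column_guard(self):
        sc = fit_scaler(np.full((3, 1), 5.0))
        out = apply_scaler(sc, np.full((3, 1), 5.0))
        npt.assert_array_equal(out, 0.0)
        npt.assert_array_equal(invert_scaler(sc, out), 5.0)

    def test_roundtrip_identity(self):
        rng = np.random.default_rng(4)
        data = rng.normal(2.0, 3.0, size=(50, 6))
        sc = fit_scaler(data)
        npt.assert_allclose(invert_scaler(sc, apply_scaler(sc, data)), data,
                            rtol=0, atol=1e-12)

    def test_unfitted_scaler_raises(self):
        from dynml import Scaler
        with pytest.raises(RuntimeError, match="not been fitted"):
            apply_scaler(Scaler(), np.zeros((2, 2)))


class TestEmbedding:
    def setup_method(self):
        self.rng = np.random.default_rng(11)
        self.params = sample_lorenz_params(3, self.rng)
        self.proj = make_projection(4, 3, self.rng)
        self.integ = IntegratorConfig(horizon=2.0)

    def test_zero_input_gives_zero_column(self):
        X = embed_dataset(np.zeros((1, 4)), self.proj, self.params,
                          self.integ)
        npt.assert_array_equal(X, 0.0)

    def test_row_permutation_permutes_columns(self):
        U = self.rng.normal(size=(6, 4))
        X = embed_dataset(U, self.proj, self.params, self.integ)
        perm = self.rng.permutation(6)
        Xp = embed_dataset(U[perm], self.proj, self.params, self.integ)
        npt.assert_array_equal(Xp, X[:, perm])

    def test_batch_matches_per_sample_loop(self):
        U = self.rng.normal(size=(5, 4))
        X = embed_dataset(U, self.proj, self.params, self.integ)
        for d in range(5):
            col = embed_dataset(U[d:d + 1], self.proj, self.params,
                                self.integ)
            npt.assert_allclose(X[:, d], col[:, 0], rtol=0, atol=1e-10)


class TestReadout:
    def test_identity_feature_block(self):
        X = np.eye(2)
        Y = np.array([[1.0, 2.0], [3.0, 4.0]])
        ro = fit_readout(TrainingBatch(X=X, Y=Y))
        npt.assert_allclose(ro.S, Y, rtol=0, atol=1e-12)

    def test_exact_construction_recovery(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(6, 40))
        S0 = rng.normal(size=(3, 6))
        ro = fit_readout(TrainingBatch(X=X, Y=S0 @ X))
        npt.assert_allclose(ro.S @ X, S0 @ X, rtol=0, atol=1e-8)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(4, 50))
        Y = rng.normal(size=(2, 50))
        ro = fit_readout(TrainingBatch(X=X, Y=Y))
        S_ne = Y @ X.T @ np.linalg.inv(X @ X.T)
        npt.assert_allclose(ro.S, S_ne, rtol=0, atol=1e-8)

    def test_minimum_norm_on_rank_deficient_block(self):
        rng = np.random.default_rng(23)
        X = np.vstack([rng.normal(size=(2, 30))] * 2)  # rank 2 of 4
        Y = rng.normal(size=(1, 30))
        ro = fit_readout(TrainingBatch(X=X, Y=Y))
        S_pinv = Y @ np.linalg.pinv(X)
        npt.assert_allclose(ro.S, S_pinv, rtol=0, atol=1e-8)

    def test_perturbation_does_not_reduce_objective(self):
        rng = np.random.default_rng(24)
        X = rng.normal(size=(3, 20))
        Y = rng.normal(size=(2, 20))
        ro = fit_readout(TrainingBatch(X=X, Y=Y))
        base = np.linalg.norm(Y - ro.S @ X) ** 2
        for _ in range(100):
            delta = rng.normal(scale=1e-3, size=ro.S.shape)
            assert np.linalg.norm(Y - (ro.S + delta) @ X) ** 2 >= base - 1e-12

    def test_nonfinite_batch_rejected(self):
        X = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError):
            fit_readout(TrainingBatch(X=X, Y=np.ones((1, 2))))

    def test_predict_special_readouts(self):
        states = np.random.default_rng(25).normal(size=(3, 7))
        zero = ReadoutMatrix(S=np.zeros((2, 3)))
        npt.assert_array_equal(predict(zero, states), 0.0)
        ident = ReadoutMatrix(S=np.eye(3))
        npt.assert_array_equal(predict(ident, states), states)


class TestClassifierReadout:
    def _clouds(self, rng, n=60, sep=6.0):
        X = np.vstack([rng.normal(0, 1, (n, 3)),
                       rng.normal(sep, 1, (n, 3))]).T
        y = np.repeat([0, 1], n)
        return X, y

    def test_separable_clouds_perfect_train_accuracy(self):
        X, y = self._clouds(np.random.default_rng(31))
        clf = fit_classifier_readout(X, y)
        assert accuracy(predict_labels(clf, X), y) == 1.0

    def test_consistent_permutation_preserves_accuracy(self):
        rng = np.random.default_rng(32)
        X, y = self._clouds(rng)
        clf = fit_classifier_readout(X, y)
        acc = accuracy(predict_labels(clf, X), y)
        perm = rng.permutation(len(y))
        clf2 = fit_classifier_readout(X[:, perm], y[perm])
        assert accuracy(predict_labels(clf2, X[:, perm]), y[perm]) == acc

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_classifier_readout(np.ones((2, 5)), np.zeros(5, dtype=int))

    def test_constant_predictor_on_balanced_labels(self):
        """Predicting one fixed class on perfectly balanced 10-class labels
        scores exactly 1/10."""
        y = np.repeat(np.arange(10), 20)
        assert accuracy(np.zeros_like(y), y) == pytest.approx(0.1)


class TestEvaluate:
    def test_perfect_and_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p, mse = evaluate(x, x)
        assert r == pytest.approx(1.0) and mse == 0.0
        r, _, _ = evaluate(-(x - x.mean()), x - x.mean())
        assert r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        r, p, _ = evaluate(np.array([1.0, 2.0, 3.0]),
                           np.array([1.0, 2.0, 4.0]))
        assert r == pytest.approx(9.0 / np.sqrt(84.0), abs=1e-12)
        assert 0.0 < p < 1.0

    def test_constant_vector_reports_nan(self):
        r, p, mse = evaluate(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)
        assert mse == pytest.approx(np.mean((1.0 - np.arange(5.0)) ** 2))

    def test_length_guard(self):
        with pytest.raises(ValueError):
            evaluate(np.ones(2), np.ones(2))
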