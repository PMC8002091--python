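"""ReLU regressors: training, R^2, cross-validation, input reduction."""

import numpy as np
import pytest

from invqsar.chemgraph import Dataset
from invqsar.descriptors import feature_vector
from invqsar.predictor import (
    CVResult,
    Predictor,
    PredictorError,
    cross_validate,
    load_model,
    r_squared,
    reduce_inputs,
    save_model,
    train,
)


@pytest.fixture(scope="module")
def linear_setup(toy_spec, toy_space, toy_extensions):
    rng = np.random.default_rng(12)
    graphs = [g for g, _ in toy_extensions[::79]]
    X = np.array([feature_vector(g, toy_space) for g in graphs])
    coef = rng.uniform(-1, 1, toy_space.K)
    y = X @ coef
    return Dataset(graphs, list(y)), toy_space, X, coef


class TestPredict:
    def test_zero_weights_output_bias(self):
        p = Predictor([np.zeros((3, 2)), np.zeros((2, 1))], [np.zeros(2), np.array([4.5])])
        assert p.predict([1, 2, 3]) == 4.5

    def test_hand_computed_single_unit(self):
        # h = relu(2x1 - x2 + 1); y = 3h - 2
        p = Predictor(
            [np.array([[2.0], [-1.0]]), np.array([[3.0]])],
            [np.array([1.0]), np.array([-2.0])],
        )
        assert p.predict([1.0, 0.5]) == pytest.approx(3 * 2.5 - 2)
        assert p.predict([-2.0, 1.0]) == pytest.approx(-2.0)  # ReLU clamps

    def test_length_mismatch(self):
        p = Predictor([np.zeros((3, 1))], [np.array([0.0])])
        with pytest.raises(PredictorError):
            p.predict([1.0])


class TestTrain:
    def test_linear_property_learned(self, linear_setup):
        ds, space, X, _ = linear_setup
        model = train(ds, space, (space.K, 8, 1), train_seed=0, X=X, solver="lbfgs", scale_inputs=True)
        assert r_squared(model, ds, space, X=X) >= 0.99

    def test_architecture_width_checked(self, linear_setup):
        ds, space, X, _ = linear_setup
        with pytest.raises(PredictorError):
            train(ds, space, (space.K + 1, 4, 1), X=X)

    def test_single_example_degenerate_fit(self, toy_space, toy_extensions):
        g = toy_extensions[0][0]
        ds = Dataset([g], [7.25])
        model = train(ds, toy_space, (toy_space.K, 4, 1))
        assert model.predict_graph(g, toy_space) == pytest.approx(7.25)
        with pytest.raises(PredictorError):
            r_squared(model, ds, toy_space)

    def test_piecewise_linear_representable(self, linear_setup):
        """max(0, c.x - t) is exactly one ReLU unit; training recovers it."""
        ds, space, X, coef = linear_setup
        y = np.maximum(X @ coef - np.median(X @ coef), 0.0)
        ds2 = Dataset(ds.graphs, list(y))
        model = train(ds2, space, (space.K, 16, 1), train_seed=1, X=X, solver="lbfgs", scale_inputs=True)
        assert r_squared(model, ds2, space, X=X) >= 0.9

    def test_scaled_training_folds_transform(self, linear_setup):
        ds, space, X, _ = linear_setup
        m = train(ds, space, (space.K, 8, 1), train_seed=0, scale_inputs=True, X=X, solver="lbfgs")
        # the returned predictor consumes *raw* descriptors
        assert r_squared(m, ds, space, X=X) >= 0.95


class TestRSquared:
    def test_perfect_and_mean_predictors(self, linear_setup):
        ds, space, X, coef = linear_setup
        perfect = Predictor(
            [coef.reshape(-1, 1), np.array([[1.0]])],
            [np.array([1000.0]), np.array([-1000.0])],
        )
        assert r_squared(perfect, ds, space, X=X) == pytest.approx(1.0)
        mean = Predictor(
            [np.zeros((space.K, 1)), np.zeros((1, 1))],
            [np.zeros(1), np.array([np.mean(ds.values)])],
        )
        assert r_squared(mean, ds, space, X=X) == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_five_points(self, toy_space, toy_extensions):
        graphs = [g for g, _ in toy_extensions[:5]]
        y = [1.0, 2.0, 3.0, 4.0, 10.0]
        preds = [1.5, 2.0, 2.5, 5.0, 9.0]
        ds = Dataset(graphs, y)

        class Stub(Predictor):
            def __init__(self):
                super().__init__([np.zeros((toy_space.K, 1))], [np.zeros(1)])
                self._i = 0

            def predict(self, x):
                v = preds[self._i % 5]
                self._i += 1
                return v

        ybar = np.mean(y)
        expected = 1 - sum((a - b) ** 2 for a, b in zip(y, preds)) / sum(
            (a - ybar) ** 2 for a in y
        )
        assert r_squared(Stub(), ds, toy_space) == pytest.approx(expected)

    def test_constant_property_undefined(self, toy_space, toy_extensions):
        ds = Dataset([g for g, _ in toy_extensions[:3]], [2.0, 2.0, 2.0])
        p = Predictor([np.zeros((toy_space.K, 1))], [np.zeros(1)])
        with pytest.raises(PredictorError):
            r_squared(p, ds, toy_space)


class TestCrossValidate:
    def test_linear_property_all_folds_good(self, linear_setup):
        ds, space, _, _ = linear_setup
        cv = cross_validate(ds, space, [(space.K, 8, 1)], fold_seed=0, train_seed=0, solver="lbfgs", scale_inputs=True)
        assert cv.best_mean >= 0.9
        assert all(r >= 0.8 for r in cv.fold_r2[(space.K, 8, 1)])

    def test_mean_is_arithmetic_mean_of_folds(self, linear_setup):
        ds, space, _, _ = linear_setup
        cv = cross_validate(ds, space, [(space.K, 4, 1)], fold_seed=1, train_seed=0)
        arch = (space.K, 4, 1)
        assert cv.mean_r2(arch) == pytest.approx(np.mean(cv.fold_r2[arch]))
        assert cv.max_r2 >= cv.best_mean

    def test_fold_membership_depends_only_on_seed(self, linear_setup):
        ds, space, _, _ = linear_setup
        perm = np.random.default_rng(0).permutation(len(ds))
        ds2 = Dataset([ds.graphs[i] for i in perm], [ds.values[i] for i in perm])
        cv1 = cross_validate(ds, space, [(space.K, 4, 1)], fold_seed=7)
        cv2 = cross_validate(ds2, space, [(space.K, 4, 1)], fold_seed=7)
        assert cv1.fold_assignment == cv2.fold_assignment


class TestReduceInputs:
    def test_identity_when_spec_keeps_everything(self, linear_setup, toy_spec):
        ds, space, X, _ = linear_setup
        model = train(ds, space, (space.K, 6, 1), train_seed=0, X=X, solver="lbfgs", scale_inputs=True)
        red, rspace = reduce_inputs(model, space, toy_spec.chemical)
        assert rspace.K == space.K
        for x in X[:10]:
            assert red.predict(x) == pytest.approx(model.predict(x))

    def test_drops_unused_slots_and_agrees_on_conforming_graphs(
        self, linear_setup, toy_spec
    ):
        import dataclasses

        ds, space, X, _ = linear_setup
        model = train(ds, space, (space.K, 6, 1), train_seed=0, X=X, solver="lbfgs", scale_inputs=True)
        keep = toy_spec.chemical.f_star()[:2]
        sub = dataclasses.replace(
            toy_spec.chemical,
            fringe_v={0: keep, 1: keep},
            fringe_e=keep,
        )
        red, rspace = reduce_inputs(model, space, sub)
        dropped = len(space.fringe_codes) - len(rspace.fringe_codes)
        assert dropped == len(space.fringe_codes) - 2
        assert red.K == space.K - dropped
        # graphs whose fringes stay inside the kept set predict identically
        for g in ds.graphs:
            try:
                xr = feature_vector(g, rspace)
            except Exception:
                continue
            assert red.predict(xr) == pytest.approx(
                model.predict(feature_vector(g, space)), abs=1e-9
            )

    def test_missing_code_raises(self, linear_setup, toy_spec):
        import dataclasses

        ds, space, X, _ = linear_setup
        model = train(ds, space, (space.K, 4, 1), X=X)
        bad = dataclasses.replace(toy_spec.chemical, fringe_e=("(S)",), fringe_v={})
        with pytest.raises(PredictorError):
            reduce_inputs(model, space, bad)


class TestSerialization:
    def test_roundtrip_bitwise(self, tmp_path, linear_setup):
        ds, space, X, _ = linear_setup
        model = train(ds, space, (space.K, 5, 1), train_seed=3, X=X)
        path = tmp_path / "model.json"
        save_model(model, space, path)
        back, space2 = load_model(path)
        assert space2.to_dict() == space.to_dict()
        for x in X[:20]:
            assert back.predict(x) == model.predict(x)  # bit-for-bit
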