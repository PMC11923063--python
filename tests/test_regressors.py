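"""Regressors: MLP training, attention gate, two-stage model, CV, grids."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enzkin.regressors import (
    MLPRegressor,
    RegressorConfig,
    TwoStageRatioModel,
    attention_gate,
    crossval,
    ensemble_predict,
    grid_search,
    predict_multi_substrate,
    train_regressor,
    train_tree_ensemble,
    train_two_stage,
)
from enzkin.splits import random_partition

FAST = RegressorConfig(hidden_dim=32, epochs=15, seed=0)


class TestAttentionGate:
    def test_zero_weights_give_uniform_attention(self):
        h = np.array([1.0, -2.0, 3.0, 0.5])
        A, hA = attention_gate(np.zeros((4, 4)), h)
        np.testing.assert_allclose(A, np.full(4, 0.25))
        np.testing.assert_allclose(hA, h / 4)

    def test_softmax_arithmetic(self):
        # scores (ln 2, 0) → attention (2/3, 1/3)
        h = np.array([1.0, 1.0])
        W = np.array([[np.log(2), 0.0], [0.0, 0.0]])
        A, _ = attention_gate(W, h)
        np.testing.assert_allclose(A, [2 / 3, 1 / 3])

    def test_vector_weight_form(self):
        h = np.array([2.0, 1.0])
        A, hA = attention_gate(np.zeros(2), h)
        np.testing.assert_allclose(A, [0.5, 0.5])
        np.testing.assert_allclose(hA, [1.0, 0.5])

    def test_batch_rows_each_normalized(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((6, 6))
        H = rng.standard_normal((10, 6))
        A, hA = attention_gate(W, H)
        np.testing.assert_allclose(A.sum(axis=1), np.ones(10), atol=1e-9)
        np.testing.assert_allclose(hA, A * H)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_attention_sums_to_one_under_fuzzing(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 16))
        W = rng.standard_normal((d, d)) * 3
        h = rng.standard_normal(d) * 5
        A, hA = attention_gate(W, h)
        assert abs(A.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(hA, A * h)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_gate(np.zeros((3, 3)), np.zeros(4))


class TestTrainRegressor:
    def test_linear_target_fits_below_005(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2000, 5))
        y = X @ rng.standard_normal(5)
        _model, history = train_regressor(X, y, RegressorConfig(seed=0))
        assert history[-1] < 0.05

    def test_constant_target_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 4))
        y = np.full(300, 2.5)
        model, _ = train_regressor(
            X, y, RegressorConfig(hidden_dim=16, epochs=60, seed=0))
        assert np.abs(model.predict(X) - 2.5).max() < 1e-3

    def test_same_seed_identical_history(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 6))
        y = rng.standard_normal(200)
        _, h1 = train_regressor(X, y, FAST)
        _, h2 = train_regressor(X, y, FAST)
        assert h1 == h2

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            train_regressor(np.zeros((5, 3)), np.zeros(4), FAST)

    def test_nonfinite_input_rejected(self):
        X = np.zeros((5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_regressor(X, np.zeros(5), FAST)

    def test_predict_checks_input_dim(self):
        model = MLPRegressor(4, FAST)
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 5)))


class TestTreeEnsemble:
    def test_seeded_run_reproducible(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((150, 4))
        y = rng.standard_normal(150)
        a = train_tree_ensemble(X, y, FAST).predict(X)
        b = train_tree_ensemble(X, y, FAST).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_fits_step_function_better_than_linear(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, size=(400, 3))
        y = np.where(X[:, 0] > 0, 2.0, -2.0)  # step in the first feature
        trees = train_tree_ensemble(X, y, FAST)
        tree_rmse = float(np.sqrt(np.mean((trees.predict(X) - y) ** 2)))
        coef, *_ = np.linalg.lstsq(
            np.column_stack([X, np.ones(len(X))]), y, rcond=None)
        linear_rmse = float(np.sqrt(np.mean(
            (np.column_stack([X, np.ones(len(X))]) @ coef - y) ** 2)))
        assert tree_rmse < linear_rmse

    def test_predict_contract_matches_neural_backend(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 4))
        y = rng.standard_normal(60)
        trees = train_tree_ensemble(X, y, FAST)
        mlp, _ = train_regressor(X, y, FAST)
        assert trees.predict(X).shape == mlp.predict(X).shape
        with pytest.raises(ValueError):
            trees.predict(np.zeros((2, 9)))


def make_two_stage_data(n=600, d=12, seed=0):
    """Ratio data whose residual after the submodel difference is linear."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    w_kcat = rng.standard_normal(d)
    w_km = rng.standard_normal(d)
    w_resid = rng.standard_normal(d) * 0.5
    y_kcat = X @ w_kcat + 0.05 * rng.standard_normal(n)
    y_km = X @ w_km + 0.05 * rng.standard_normal(n)
    y_ratio = (X @ w_kcat - X @ w_km) + X @ w_resid
    return X, y_ratio, y_kcat, y_km


class TestTwoStageModel:
    def test_zero_correction_equals_log_difference_exactly(self):
        m1 = MLPRegressor(8, RegressorConfig(hidden_dim=8, seed=1))
        m2 = MLPRegressor(8, RegressorConfig(hidden_dim=8, seed=2))
        model = TwoStageRatioModel(m1, m2,
                                   RegressorConfig(hidden_dim=8, seed=3))
        model.correction_net.zero_output()
        x = np.random.default_rng(0).standard_normal((10, 8))
        np.testing.assert_array_equal(model.predict(x),
                                      model.raw_difference(x))

    def test_correction_only_when_blend_a_zero(self):
        m1 = MLPRegressor(8, RegressorConfig(hidden_dim=8, seed=1))
        m2 = MLPRegressor(8, RegressorConfig(hidden_dim=8, seed=2))
        model = TwoStageRatioModel(m1, m2,
                                   RegressorConfig(hidden_dim=8, seed=3))
        model.blend[:] = [0.0, 1.0]
        x = np.random.default_rng(0).standard_normal((10, 8))
        np.testing.assert_allclose(model.predict(x),
                                   model.correction_net.predict(x))

    def test_submodels_frozen_through_correction_training(self):
        X, y_ratio, y_kcat, y_km = make_two_stage_data(n=200, seed=6)
        cfg = RegressorConfig(hidden_dim=16, epochs=10, seed=0)
        m1 = MLPRegressor(X.shape[1], cfg).fit(X, y_kcat)
        m2 = MLPRegressor(X.shape[1], cfg.with_seed(1)).fit(X, y_km)
        model = TwoStageRatioModel(m1, m2, cfg.with_seed(2))
        before = model.submodel_digests()
        model.fit_correction(X, y_ratio)
        assert model.submodel_digests() == before

    def test_full_batch_loss_nonincreasing_at_small_lr(self):
        X, y_ratio, y_kcat, y_km = make_two_stage_data(n=64, seed=7)
        cfg = RegressorConfig(hidden_dim=16, epochs=10, seed=0)
        m1 = MLPRegressor(X.shape[1], cfg).fit(X, y_kcat)
        m2 = MLPRegressor(X.shape[1], cfg.with_seed(1)).fit(X, y_km)
        slow = RegressorConfig(hidden_dim=16, epochs=25, batch_size=64,
                               learning_rate=1e-4, seed=2)
        model = TwoStageRatioModel(m1, m2, slow)
        model.fit_correction(X, y_ratio)
        diffs = np.diff(model.loss_history)
        assert (diffs <= 1e-6).all()

    def test_correction_beats_raw_difference_on_learnable_residual(self):
        X, y_ratio, y_kcat, y_km = make_two_stage_data(seed=0)
        keys = list(range(len(X)))
        folds = random_partition(keys, k=4, seed=0)
        cfg = RegressorConfig(hidden_dim=32, epochs=25, seed=0)
        res = train_two_stage(X, y_ratio, y_kcat, y_km, keys, folds,
                              cfg, cfg)
        assert res.two_stage_rmse < res.raw_difference_rmse

    def test_missing_parent_labels_rejected(self):
        X, y_ratio, y_kcat, y_km = make_two_stage_data(n=50, seed=8)
        y_kcat[0] = np.nan
        keys = list(range(len(X)))
        folds = random_partition(keys, k=2, seed=0)
        with pytest.raises(ValueError, match="parent"):
            train_two_stage(X, y_ratio, y_kcat, y_km, keys, folds,
                            FAST, FAST)


class TestCrossval:
    def setup_method(self):
        rng = np.random.default_rng(9)
        self.X = rng.standard_normal((80, 6))
        self.y = self.X @ rng.standard_normal(6)
        self.keys = [f"r{i}" for i in range(80)]

    def test_every_record_predicted_exactly_once(self):
        folds = random_partition(self.keys, k=2, seed=0)
        res = crossval(self.X, self.y, self.keys, folds, FAST)
        assert np.isfinite(res.oof_pred).all()

    def test_same_seed_identical_oof(self):
        folds = random_partition(self.keys, k=4, seed=1)
        a = crossval(self.X, self.y, self.keys, folds, FAST)
        b = crossval(self.X, self.y, self.keys, folds, FAST)
        np.testing.assert_array_equal(a.oof_pred, b.oof_pred)

    def test_missing_key_rejected(self):
        folds = random_partition(self.keys[:-1], k=2, seed=0)
        with pytest.raises(ValueError):
            crossval(self.X, self.y, self.keys, folds, FAST)

    def test_summary_renders(self):
        folds = random_partition(self.keys, k=2, seed=0)
        res = crossval(self.X, self.y, self.keys, folds, FAST)
        text = res.summary()
        assert "pooled OOF" in text and "PCC" in text


class TestGridSearch:
    def test_singleton_grid_returned(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        keys = list(range(40))
        folds = random_partition(keys, k=2, seed=0)
        best, table = grid_search(X, y, keys, folds, [FAST])
        assert best == FAST and len(table) == 1

    def test_dominated_config_not_selected(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((200, 5))
        y = X @ rng.standard_normal(5)
        keys = list(range(200))
        folds = random_partition(keys, k=2, seed=0)
        good = RegressorConfig(hidden_dim=32, epochs=25, seed=0)
        bad = RegressorConfig(hidden_dim=32, epochs=0, seed=0)  # untrained
        best, table = grid_search(X, y, keys, folds, [bad, good])
        assert best == good
        assert len(table) == 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((4, 2)), np.zeros(4), [0, 1, 2, 3],
                        random_partition(range(4), k=2, seed=0), [])


class TestEnsemble:
    def test_identical_members_equal_single_model(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        model, _ = train_regressor(X, y, FAST)
        np.testing.assert_allclose(ensemble_predict([model, model], X),
                                   model.predict(X))

    def test_arithmetic_mean(self):
        class Const:
            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(len(X), self.v)

        out = ensemble_predict([Const(1.0), Const(3.0)], np.zeros((5, 2)))
        np.testing.assert_allclose(out, 2.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([], np.zeros((2, 2)))

    def test_single_substrate_reaction_equals_direct_prediction(self):
        from enzkin.featurization import feature_matrix, synthetic_provider

        pp = synthetic_provider(8, seed=0, mode="kmer_composition")
        mp = synthetic_provider(4, seed=1)
        rng = np.random.default_rng(13)
        X = rng.standard_normal((30, 8 + 4 + 167))
        model, _ = train_regressor(X, rng.standard_normal(30), FAST)
        single = predict_multi_substrate(model, "MKTAYIAK", ["CCO"], pp, mp)
        direct = model.predict(
            feature_matrix([("MKTAYIAK", "CCO")], pp, mp))[0]
        assert single == pytest.approx(direct)

    def test_multi_substrate_is_mean_over_substrates(self):
        from enzkin.featurization import feature_matrix, synthetic_provider

        pp = synthetic_provider(8, seed=0, mode="kmer_composition")
        mp = synthetic_provider(4, seed=1)
        rng = np.random.default_rng(14)
        X = rng.standard_normal((30, 8 + 4 + 167))
        model, _ = train_regressor(X, rng.standard_normal(30), FAST)
        smiles = ["CCO", "CC(=O)O", "c1ccccc1O"]
        combined = predict_multi_substrate(model, "MKTAYIAK", smiles, pp, mp)
        per_sub = [model.predict(
            feature_matrix([("MKTAYIAK", s)], pp, mp))[0] for s in smiles]
        assert combined == pytest.approx(np.mean(per_sub))
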