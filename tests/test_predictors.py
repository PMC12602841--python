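"""Trainable predictor: OLS oracle recovery, backprop correctness, evaluation utilities."""

import numpy as np
import pandas as pd
import pytest

from fedbioage.cohorts import CohortSpec, GeneratorTruth, generate_cohort
from fedbioage.predictors import (
    AgePredictor,
    PredictorConfig,
    bootstrap_ci_mae,
    kfold_cv,
    mae,
    predict_age,
    train_predictor,
)

from conftest import make_linear_table


class TestTraining:
    def test_linear_recovers_noise_free_line_vs_ols_oracle(self):
        # y = 2 x + 1 exactly; closed-form least squares is the oracle
        t = make_linear_table(n=80, slope=2.0, intercept=1.0, noise_sd=0.0, seed=0)
        cfg = PredictorConfig(
            kind="linear", feature_cols=("f0",), sex_concat=False,
            learning_rate=5e-2, lr_decay=0.0, optimizer="adam",
        )
        params = train_predictor(t, t, cfg, epochs=3000, seed=1, batch_size=None)
        X = np.column_stack([t["f0"], np.ones(len(t))])
        w_ols, b_ols = np.linalg.lstsq(X, t["age"].to_numpy(), rcond=None)[0]
        assert params.get("W0")[0] == pytest.approx(w_ols, abs=1e-3)
        assert params.get("b0")[0] == pytest.approx(b_ols, abs=1e-3)
        assert w_ols == pytest.approx(2.0, abs=1e-10)

    def test_zero_epochs_returns_initialization(self):
        t = make_linear_table(20, 1.0, 0.0, 1.0, seed=2)
        cfg = PredictorConfig(kind="linear", feature_cols=("f0",), sex_concat=False)
        model = AgePredictor(cfg)
        params = train_predictor(t, t, cfg, epochs=0, seed=9)
        np.testing.assert_array_equal(params.values, model.init_params(9).values)

    def test_full_batch_loss_non_increasing(self):
        t = make_linear_table(60, 1.5, 3.0, 2.0, seed=3)
        cfg = PredictorConfig(
            kind="linear", feature_cols=("f0",), sex_concat=False,
            learning_rate=1e-4, lr_decay=0.0, optimizer="sgd",
        )
        model = AgePredictor(cfg)
        params = model.init_params(0)
        losses = [model.loss(params, t)]
        for _ in range(20):
            params, _ = model.train(params, t, 1, None)
            losses.append(model.loss(params, t))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_mlp_gradient_matches_finite_differences(self):
        t = make_linear_table(12, 1.0, 5.0, 1.0, seed=4)
        cfg = PredictorConfig(kind="mlp", feature_cols=("f0",), hidden_sizes=(5, 3))
        model = AgePredictor(cfg)
        params = model.init_params(2)
        X, sex, y = model._inputs(t)
        grad, _ = model._gradient(params, X, sex, y)
        eps = 1e-6
        for j in range(0, model.n_params, 3):
            up, dn = params.values.copy(), params.values.copy()
            up[j] += eps
            dn[j] -= eps
            num = (model.loss(model._pv(up), t) - model.loss(model._pv(dn), t)) / (2 * eps)
            assert grad[j] == pytest.approx(num, abs=1e-5)

    def test_cnn_gradient_matches_finite_differences(self):
        truth = GeneratorTruth()
        spec = CohortSpec("V", 8, 45, 90, age_mean=65, age_sd=10, volumetric=True, seed=5)
        t = generate_cohort(spec, truth)
        cfg = PredictorConfig(kind="cnn3d_small", hidden_sizes=())
        model = AgePredictor(cfg)
        params = model.init_params(3)
        X, sex, y = model._inputs(t)
        grad, _ = model._gradient(params, X, sex, y)
        eps = 1e-6
        for j in list(range(0, model.n_params, 17)) + [model.n_params - 1]:
            up, dn = params.values.copy(), params.values.copy()
            up[j] += eps
            dn[j] -= eps
            num = (model.loss(model._pv(up), t) - model.loss(model._pv(dn), t)) / (2 * eps)
            assert grad[j] == pytest.approx(num, rel=1e-4, abs=1e-4)

    def test_cnn_training_reduces_loss(self):
        truth = GeneratorTruth()
        spec = CohortSpec("V", 60, 45, 90, age_mean=65, age_sd=10, volumetric=True, seed=6)
        t = generate_cohort(spec, truth)
        cfg = PredictorConfig(kind="cnn3d_small", hidden_sizes=(), learning_rate=5e-3)
        model = AgePredictor(cfg)
        p0 = model.init_params(0)
        p1, _ = model.train(p0, t, 10, 8, seed=0)
        assert model.loss(p1, t) < model.loss(p0, t)


class TestPredict:
    @pytest.fixture(scope="class")
    def trained(self):
        t = make_linear_table(50, 1.0, 0.0, 1.0, seed=7)
        cfg = PredictorConfig(
            kind="mlp", feature_cols=("f0",), hidden_sizes=(8,), dropout_last=0.5,
        )
        params = train_predictor(t, t, cfg, epochs=3, seed=0)
        return t, cfg, params

    def test_dropout_inference_deterministic(self, trained):
        t, cfg, params = trained
        a = predict_age(params, t, cfg)
        b = predict_age(params, t, cfg)
        np.testing.assert_array_equal(a, b)

    def test_permutation_equivariance(self, trained):
        t, cfg, params = trained
        perm = np.random.default_rng(0).permutation(len(t))
        np.testing.assert_allclose(
            predict_age(params, t.iloc[perm], cfg), predict_age(params, t, cfg)[perm]
        )

    def test_duplicate_row_duplicate_prediction(self, trained):
        t, cfg, params = trained
        doubled = pd.concat([t.head(1), t.head(1)], ignore_index=True)
        pred = predict_age(params, doubled, cfg)
        assert pred[0] == pred[1]

    def test_layout_mismatch_rejected(self, trained):
        t, cfg, params = trained
        other = PredictorConfig(kind="linear", feature_cols=("f0",))
        with pytest.raises(ValueError, match="layout"):
            predict_age(params, t, other)

    def test_identity_params_reproduce_age(self):
        # w = 1 on a single feature equal to age, b = 0 -> predictions == age
        t = make_linear_table(20, 1.0, 0.0, 0.0, seed=8)
        cfg = PredictorConfig(kind="linear", feature_cols=("f0",), sex_concat=False)
        model = AgePredictor(cfg)
        params = model._pv(np.array([1.0, 0.0]))
        np.testing.assert_allclose(predict_age(params, t, cfg), t["f0"].to_numpy())


class TestMetrics:
    def test_mae_arithmetic(self):
        assert mae([60.0, 70.0], [62.0, 66.0]) == pytest.approx(3.0)
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mae(np.array([4.0, 5.0]) + 3, [4.0, 5.0]) == pytest.approx(3.0)

    def test_mae_empty_rejected(self):
        with pytest.raises(ValueError):
            mae([], [])

    def test_bootstrap_degenerate_constant_error(self):
        age = np.arange(50.0, 60.0)
        lo, hi = bootstrap_ci_mae(age + 3, age, resamples=200, seed=0)
        assert (lo, hi) == (3.0, 3.0)

    def test_bootstrap_single_resample(self):
        age = np.arange(50.0, 60.0)
        pred = age + np.random.default_rng(0).normal(0, 2, 10)
        lo, hi = bootstrap_ci_mae(pred, age, resamples=1, seed=1)
        assert lo == hi

    def test_bootstrap_interval_usually_contains_point_mae(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(50, 90, 120)
        pred = age + rng.normal(0, 3, 120)
        point = mae(pred, age)
        hits = sum(
            lo <= point <= hi
            for lo, hi in (bootstrap_ci_mae(pred, age, 1000, 0.95, seed=s) for s in range(30))
        )
        assert hits >= 29

    def test_bootstrap_width_scales_inverse_sqrt_n(self):
        rng = np.random.default_rng(6)
        n = 400
        age = rng.uniform(50, 90, 4 * n)
        pred = age + rng.normal(0, 3, 4 * n)

        def width(k):
            lo, hi = bootstrap_ci_mae(pred[:k], age[:k], 2000, 0.95, seed=2)
            return hi - lo

        ratio = width(n) / width(4 * n)
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci_mae([1.0], [1.0], level=1.5)


class TestKFold:
    def test_equal_fold_sizes(self):
        t = make_linear_table(9, 1.0, 0.0, 0.0, seed=9)
        seen = []

        def trainer(train):
            seen.append(len(train))
            return lambda tab: tab["age"].to_numpy()

        maes = kfold_cv(t, 3, trainer, seed=0)
        assert seen == [6, 6, 6]
        assert maes == [0.0, 0.0, 0.0]  # perfect oracle trainer

    def test_fold_assignment_reproducible(self):
        t = make_linear_table(12, 1.0, 0.0, 1.0, seed=10)
        folds = []

        def trainer(train):
            folds.append(tuple(sorted(train["participant_id"])))
            return lambda tab: tab["age"].to_numpy()

        kfold_cv(t, 3, trainer, seed=4)
        first = list(folds)
        folds.clear()
        kfold_cv(t, 3, trainer, seed=4)
        assert folds == first

    def test_k_larger_than_n_rejected(self):
        t = make_linear_table(3, 1.0, 0.0, 0.0, seed=11)
        with pytest.raises(ValueError):
            kfold_cv(t, 5, lambda train: (lambda tab: tab["age"].to_numpy()), seed=0)
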