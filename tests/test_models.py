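"""Model building, training protocol, baselines, classical models, tuning."""

import numpy as np
import pytest

from synscreen.evaluation import compute_scores, random_split
from synscreen.nn import (
    ModelConfig,
    SearchSpace,
    SubnetworkSpec,
    TrainConfig,
    build_multimodal,
    fit_classical,
    mean_baseline,
    train,
    tune,
)
from synscreen.nn.classical import CLASSICAL_KINDS
from synscreen.pipeline import build_dataset, input_shapes, scale_expression, take_inputs


def _dense_config(lr=2e-3, **kwargs):
    return ModelConfig(
        expr_spec=SubnetworkSpec("expr", "dense", (16,)),
        drug_spec=SubnetworkSpec("drug", "dense", (16,)),
        head_layer_sizes=(16,),
        learning_rate=lr,
        **kwargs,
    )


def _random_inputs(rng, n, expr_dim=10, drug_dim=12):
    return {
        "expr": rng.random((n, expr_dim)),
        "drug_a": rng.random((n, drug_dim)),
        "drug_b": rng.random((n, drug_dim)),
    }


class TestBuildMultimodal:
    def test_shared_drug_encoder_identical_outputs(self, rng):
        model = build_multimodal(_dense_config(), {"expr": (10,), "drug": (12,)}, seed=0)
        x = rng.random((4, 12))
        np.testing.assert_array_equal(
            model.drug_encoder(x).data, model.drug_encoder(x).data
        )
        inputs = {"expr": rng.random((4, 10)), "drug_a": x, "drug_b": x}
        # with identical drug inputs, both encoder paths contribute identically
        enc_a = model.drug_encoder(inputs["drug_a"]).data
        enc_b = model.drug_encoder(inputs["drug_b"]).data
        np.testing.assert_array_equal(enc_a, enc_b)

    def test_parameter_count_counts_drug_encoder_once(self):
        model = build_multimodal(_dense_config(), {"expr": (10,), "drug": (12,)}, seed=0)
        expr_params = sum(p.data.size for p in model.encoders["expr"].parameters())
        drug_params = sum(p.data.size for p in model.drug_encoder.parameters())
        head_params = sum(p.data.size for p in model.head.parameters())
        # an unshared design would add drug_params a second time
        assert model.n_parameters() == expr_params + drug_params + head_params

    def test_linear_output_can_be_negative(self, rng):
        model = build_multimodal(_dense_config(), {"expr": (10,), "drug": (12,)}, seed=0)
        weights = model.get_weights()
        weights[-1] = np.array([-100.0])  # head output bias
        model.set_weights(weights)
        preds = model.predict(_random_inputs(rng, 5))
        assert preds.shape == (5, 1)
        assert (preds < 0).all()

    def test_family_shape_mismatch_rejected(self):
        cfg = ModelConfig(
            expr_spec=SubnetworkSpec("expr", "conv2d", (4,)),
            drug_spec=SubnetworkSpec("drug", "dense", (8,)),
            learning_rate=1e-3,
        )
        with pytest.raises(ValueError, match="conv2d"):
            build_multimodal(cfg, {"expr": (10,), "drug": (12,)}, seed=0)

    def test_mut_subnetwork_must_be_dense(self):
        with pytest.raises(ValueError, match="fully connected"):
            ModelConfig(
                expr_spec=SubnetworkSpec("expr", "dense", (8,)),
                drug_spec=SubnetworkSpec("drug", "dense", (8,)),
                mut_spec=SubnetworkSpec("mut", "conv1d", (8,)),
            )


class TestTrainingProtocol:
    def test_fits_noiseless_linear_signal(self, rng):
        n = 400
        inputs = _random_inputs(rng, n)
        beta_e, beta_d = rng.normal(size=10), rng.normal(size=12)
        y = inputs["expr"] @ beta_e + (inputs["drug_a"] + inputs["drug_b"]) @ beta_d
        split = random_split(n, seed=0)
        cfg = TrainConfig(max_epochs=120, early_stop_patience=20, seed=0)
        model = build_multimodal(_dense_config(lr=5e-3), {"expr": (10,), "drug": (12,)}, seed=0)
        history = train(
            model,
            (take_inputs(inputs, split.train), y[split.train]),
            (take_inputs(inputs, split.val), y[split.val]),
            cfg,
        )
        final_mse = history["train_loss"][-1]
        assert final_mse < 1e-2 * y.var()

    def test_constant_targets_converge_to_constant(self, rng):
        """With weight decay, the optimum for constant targets is the
        constant predictor (all weights shrink, the output bias carries
        the mean)."""
        n = 60
        inputs = _random_inputs(rng, n)
        y = np.full(n, 7.0)
        config = ModelConfig(
            expr_spec=SubnetworkSpec("expr", "dense", (8,), activation="tanh", l2_penalty=1e-2),
            drug_spec=SubnetworkSpec("drug", "dense", (8,), activation="tanh", l2_penalty=1e-2),
            head_layer_sizes=(8,),
            head_activation="tanh",
            head_l2_penalty=1e-2,
            learning_rate=1e-2,
        )
        model = build_multimodal(config, {"expr": (10,), "drug": (12,)}, seed=1)
        history = train(
            model,
            (take_inputs(inputs, np.arange(40)), y[:40]),
            (take_inputs(inputs, np.arange(40, 60)), y[40:]),
            TrainConfig(max_epochs=400, early_stop_patience=80, seed=1),
        )
        assert min(history["val_loss"]) < 1e-2
        preds = model.predict(take_inputs(inputs, np.arange(40, 60)))
        assert preds.std() < 0.1  # effectively a constant predictor

    def test_early_stopping_protocol(self, rng):
        n = 80
        inputs = _random_inputs(rng, n)
        y = rng.normal(size=n)  # pure noise: validation loss stalls quickly
        model = build_multimodal(_dense_config(lr=1e-2), {"expr": (10,), "drug": (12,)}, seed=2)
        cfg = TrainConfig(max_epochs=200, early_stop_patience=5, seed=2)
        history = train(
            model,
            (take_inputs(inputs, np.arange(60)), y[:60]),
            (take_inputs(inputs, np.arange(60, 80)), y[60:]),
            cfg,
        )
        val = history["val_loss"]
        assert len(val) <= cfg.max_epochs
        best = history["best_epoch"]
        if len(val) < cfg.max_epochs:  # stopped early
            assert len(val) - 1 - best == cfg.early_stop_patience
            assert all(v >= val[best] for v in val[best + 1 :])
        # restored weights reproduce the best validation loss
        restored = float(
            np.mean(
                (
                    model.predict(take_inputs(inputs, np.arange(60, 80))).ravel()
                    - y[60:]
                )
                ** 2
            )
        )
        assert restored == pytest.approx(min(val), rel=1e-9)

    def test_empty_partition_rejected(self, rng):
        model = build_multimodal(_dense_config(), {"expr": (10,), "drug": (12,)}, seed=0)
        inputs = _random_inputs(rng, 10)
        empty = take_inputs(inputs, np.array([], dtype=int))
        with pytest.raises(ValueError, match="non-empty"):
            train(model, (empty, np.array([])), (inputs, np.zeros(10)))

    def test_invalid_train_config(self):
        with pytest.raises(ValueError, match="patience"):
            TrainConfig(max_epochs=10, early_stop_patience=10)


class TestMeanBaseline:
    def test_predicts_train_mean(self, rng):
        baseline = mean_baseline([1.0, 2.0, 3.0])
        assert np.all(baseline.predict(rng.random((5, 2))) == 2.0)

    def test_r2_on_own_training_set_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        baseline = mean_baseline(y)
        report = compute_scores(y, baseline.predict(np.zeros((4, 1))))
        assert report.r2 == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_features(self, rng):
        baseline = mean_baseline([5.0, 7.0])
        a = baseline.predict(rng.random((3, 4)))
        b = baseline.predict(rng.random((3, 9)) * 100)
        np.testing.assert_array_equal(a, b)


class TestClassical:
    def test_all_kinds_share_contract(self, rng):
        X = rng.random((40, 6))
        y = X @ rng.normal(size=6)
        for kind in CLASSICAL_KINDS:
            model = fit_classical(kind, X, y)
            preds = model.predict(X)
            assert np.asarray(preds).shape == (40,)

    def test_elastic_net_recovers_coefficients(self, rng):
        X = rng.normal(size=(300, 5))
        beta = np.array([2.0, -1.5, 0.7, 3.1, -0.4])
        y = X @ beta
        model = fit_classical("elastic_net", X, y, {"alpha": 1e-4, "l1_ratio": 0.5})
        np.testing.assert_allclose(model.coef_, beta, rtol=0.05)

    def test_random_forest_on_noiseless_screen(self, noiseless_bundle):
        inputs, y = build_dataset(noiseless_bundle, "morgan")
        split = random_split(len(y), seed=0)
        inputs, _ = scale_expression(inputs, split)
        X = np.hstack([inputs["expr"], inputs["drug_a"], inputs["drug_b"]])
        model = fit_classical(
            "random_forest", X[split.train], y[split.train], {"n_estimators": 200}
        )
        heldout = np.concatenate([split.val, split.test])
        report = compute_scores(y[heldout], model.predict(X[heldout]))
        assert report.r2 >= 0.8

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown classical"):
            fit_classical("quantum_svm", np.zeros((2, 2)), np.zeros(2))

    def test_non_finite_features_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_classical("elastic_net", np.array([[np.nan]]), np.array([1.0]))


class TestTune:
    @staticmethod
    def _quadratic_evaluator(noise_scale=0.0, seed=0):
        rng = np.random.default_rng(seed)

        def evaluate(config, resource):
            loss = (config["lr"] - 0.3) ** 2 + 0.1 * (config["width"] != 32)
            return loss + noise_scale * abs(rng.normal()) / resource
        return evaluate

    def test_budget_one_returns_single_config(self):
        space = SearchSpace({"lr": [0.1], "width": [16]}, budget=1, seed=0)
        best, trials = tune(self._quadratic_evaluator(), space)
        assert best == {"lr": 0.1, "width": 16}
        assert len(trials) == 1

    def test_returns_minimal_validation_mse_config(self):
        space = SearchSpace(
            {"lr": {"low": 0.01, "high": 1.0, "log": True}, "width": [16, 32]},
            budget=20,
            seed=3,
        )
        best, trials = tune(self._quadratic_evaluator(), space)
        completed = [t for t in trials if "val_mse" in t]
        best_trial = min(completed, key=lambda t: t["val_mse"])
        assert best == best_trial["config"]
        assert len({id(t["config"]) for t in trials[:20]}) <= space.budget

    def test_budget_respected(self):
        space = SearchSpace(
            {"lr": {"low": 0.01, "high": 1.0}, "width": [16, 32]}, budget=50, seed=0
        )
        _, trials = tune(self._quadratic_evaluator(), space)
        first_rung = [t for t in trials if t["resource"] == 5]
        assert len(first_rung) <= 50

    def test_planted_optimum_selected_across_seeds(self):
        """With the optimum among 8 candidates, it wins in >= 9/10 seeds."""
        candidates = [
            {"lr": lr, "width": w}
            for lr in (0.05, 0.3, 0.9, 2.0)
            for w in (16, 32)
        ]
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)

            def suggester(r, space, history, _c=iter(candidates)):
                return next(_c)

            space = SearchSpace({"lr": [0.0], "width": [0]}, budget=8, seed=seed)
            best, _ = tune(
                self._quadratic_evaluator(noise_scale=0.05, seed=seed),
                space,
                suggester=suggester,
            )
            wins += best == {"lr": 0.3, "width": 32}
        assert wins >= 9

    def test_all_failures_raise(self):
        def broken(config, resource):
            raise RuntimeError("boom")

        space = SearchSpace({"lr": [0.1]}, budget=2, seed=0)
        with pytest.raises(RuntimeError, match="failed"):
            tune(broken, space)

    def test_failed_trials_logged_and_skipped(self):
        def flaky(config, resource):
            if config["lr"] > 0.5:
                raise ValueError("diverged")
            return config["lr"]

        space = SearchSpace({"lr": [0.1, 0.9]}, budget=10, seed=1)
        best, trials = tune(flaky, space)
        assert best["lr"] == 0.1
        assert any("error" in t for t in trials)
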