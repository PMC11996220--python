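"""Constrained network: forward pass, parameter accounting, training
dynamics, frozen-mask invariance and evaluation metrics."""

import copy

import numpy as np
import pandas as pd
import pytest

from pathwaynet import (
    ConstrainedPathwayClassifier,
    DenseBaselineClassifier,
    ModelConfig,
    count_parameters,
    evaluate_predictions,
)
from pathwaynet._nn import softmax


def _fit_toy(toy_masks, n_clinical=2, seed=0, **kw):
    """Fit the constrained model on a tiny random cohort."""
    rng = np.random.default_rng(seed)
    n = 48
    X = rng.uniform(size=(n, 3 + 3 + n_clinical))
    y = rng.integers(0, 3, size=n)
    kw.setdefault("max_epochs", 3)
    clf = ConstrainedPathwayClassifier(
        mask_snp=copy.deepcopy(toy_masks), mask_expr=copy.deepcopy(toy_masks),
        random_state=seed, validation_fraction=0.25, **kw,
    )
    return clf.fit(X, y), X, y


class TestForwardPass:
    def test_subnetwork_is_masked_matrix_product(self, toy_masks):
        clf, _, _ = _fit_toy(toy_masks)
        x = np.array([[1.0, 0.5, 0.25, 0, 0, 0, 0, 0]])
        out = clf.net_.subnet_forward(x, 0)
        oracle = x[:, :3] @ toy_masks.masks[0] @ toy_masks.masks[1] @ toy_masks.masks[2]
        np.testing.assert_allclose(out, oracle)
        assert out[0, 0] == pytest.approx(1.75)  # (1 + 0.5)*1 + 0.25*1

    def test_zero_input_gives_zero_subnet_output(self, toy_masks):
        clf, _, _ = _fit_toy(toy_masks)
        assert (clf.net_.subnet_forward(np.zeros((2, 8)), 1) == 0).all()

    def test_softmax_head_normalised(self, toy_masks):
        clf, X, _ = _fit_toy(toy_masks)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert (proba >= 0).all()

    def test_tanh_subnetwork_option(self, toy_masks):
        clf, _, _ = _fit_toy(toy_masks, subnetwork_activation="tanh")
        x = np.zeros((1, 8)); x[0, :3] = (1.0, 0.5, 0.25)
        out = clf.net_.subnet_forward(x, 0)
        h = np.tanh(x[:, :3] @ toy_masks.masks[0])
        h = np.tanh(h @ toy_masks.masks[1])
        np.testing.assert_allclose(out, np.tanh(h @ toy_masks.masks[2]))


class TestParameterCounts:
    def test_counts_match_layer_walk_oracle(self, toy_masks):
        n_clin = 2
        clf, _, _ = _fit_toy(toy_masks, n_clinical=n_clin)
        counts = count_parameters(clf)
        D = 1 + 1 + n_clin  # two subnet tops + clinical
        trainable = 2 * D + (D + 1) * 19 + (19 + 1) * 8 + (8 + 1) * 3
        non_trainable = 2 * 6 + 2 * D  # two mask stacks of 6 nonzeros + BN stats
        assert counts["trainable"] == trainable
        assert counts["non_trainable"] == non_trainable
        assert counts["total"] == trainable + non_trainable
        assert counts["layer_count"] == 15
        assert counts["subnetwork_parameters"] == [6, 6]

    def test_doubling_clinical_width_difference(self, toy_masks):
        a = count_parameters(_fit_toy(toy_masks, n_clinical=2)[0])
        b = count_parameters(_fit_toy(toy_masks, n_clinical=4)[0])
        # 2 extra BN gamma/beta pairs + 2 extra rows into dense(19)
        assert b["trainable"] - a["trainable"] == 2 * 2 + 2 * 19

    def test_baseline_strictly_more_trainable(self, toy_masks):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(48, 8)); y = rng.integers(0, 3, 48)
        base = DenseBaselineClassifier(
            mask_snp=copy.deepcopy(toy_masks), mask_expr=copy.deepcopy(toy_masks),
            max_epochs=2, random_state=0,
        ).fit(X, y)
        constrained = _fit_toy(toy_masks)[0]
        assert count_parameters(base)["trainable"] > count_parameters(constrained)["trainable"]
        # dense-formula oracle for the baseline subnets (no biases)
        dense_subnet = 3 * 2 + 2 * 1 + 1 * 1
        diff = count_parameters(base)["trainable"] - count_parameters(constrained)["trainable"]
        assert diff == 2 * dense_subnet


class TestTraining:
    def test_separable_cohort_reaches_perfect_training_accuracy(self, toy_masks):
        rng = np.random.default_rng(0)
        n = 60
        y = np.repeat([0, 1, 2], 20)
        X = rng.uniform(0, 0.05, size=(n, 8))
        X[:, 6] = y / 2.0  # clinical feature linearly separating classes
        clf = ConstrainedPathwayClassifier(
            mask_snp=copy.deepcopy(toy_masks), mask_expr=copy.deepcopy(toy_masks),
            random_state=0, validation_fraction=0.2, dropout_rate=0.0,
        ).fit(X, y)
        proba = clf.predict_proba(X)
        assert (proba.argmax(1) == y).mean() == 1.0

    def test_constant_features_trigger_early_stopping(self, toy_masks):
        X = np.full((60, 8), 0.5)
        y = np.repeat([0, 1, 2], 20)
        clf = ConstrainedPathwayClassifier(
            mask_snp=copy.deepcopy(toy_masks), mask_expr=copy.deepcopy(toy_masks),
            random_state=0, max_epochs=120, patience=10,
        ).fit(X, y)
        assert clf.history_["stopped_epoch"] < 119

    def test_same_seed_identical_history(self, toy_masks):
        a = _fit_toy(toy_masks, seed=7, max_epochs=6)[0]
        b = _fit_toy(toy_masks, seed=7, max_epochs=6)[0]
        np.testing.assert_array_equal(a.history_["val_loss"], b.history_["val_loss"])
        assert a.history_["val_loss"][-1] == b.history_["val_loss"][-1]

    def test_learning_rate_schedule_closed_form(self, toy_masks):
        clf, _, _ = _fit_toy(toy_masks, max_epochs=40, patience=40)
        lrs = clf.history_["lr_steps"]
        for step in (0, 17, 34):
            assert lrs[step] == pytest.approx(0.008 * 0.96 ** (step // 17))

    def test_frozen_weights_bitwise_after_training(self, planted_run):
        _, mask_snp, mask_expr, model, _, _ = planted_run
        weights = model.subnetwork_weights()
        for w, m in zip(weights[0], mask_snp.masks):
            assert (w == m).all()
        for w, m in zip(weights[1], mask_expr.masks):
            assert (w == m).all()

    def test_gradient_isolation_frozen_layers(self, toy_masks):
        clf, _, _ = _fit_toy(toy_masks)
        before = [l.W.copy() for stack in clf.net_.subnets for l in stack]
        # frozen layers never accumulate gradients: dW buffers stay zero
        for stack in clf.net_.subnets:
            for layer in stack:
                assert np.linalg.norm(layer.dW) == 0.0
        after = [l.W for stack in clf.net_.subnets for l in stack]
        for a, b in zip(before, after):
            np.testing.assert_array_equal(a, b)

    def test_baseline_subnets_do_train(self, toy_masks):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(48, 8)); y = rng.integers(0, 3, 48)
        base = DenseBaselineClassifier(
            mask_snp=copy.deepcopy(toy_masks), mask_expr=copy.deepcopy(toy_masks),
            max_epochs=2, random_state=1,
        )
        base.fit(X, y)
        for stack in base.net_.subnets:
            for layer in stack:
                assert not layer.frozen


class TestModelConfig:
    def test_defaults_match_published_configuration(self):
        cfg = ModelConfig()
        assert (cfg.hidden1_size, cfg.hidden2_size) == (19, 8)
        assert cfg.dropout_rate == 0.597
        assert (cfg.learning_rate, cfg.decay_rate, cfg.decay_steps) == (0.008, 0.96, 17)
        assert (cfg.batch_size, cfg.max_epochs) == (32, 120)

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)

    def test_depth_mismatch_rejected(self, toy_masks):
        with pytest.raises(ValueError, match="depth"):
            ConstrainedPathwayClassifier.from_config(
                toy_masks, toy_masks, ModelConfig(depth=5)
            )


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.repeat([0, 1, 2], 10)
        proba = np.eye(3)[y]
        rep = evaluate_predictions(y, proba)
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0

    def test_hand_counted_contingency(self):
        # confusion rows CN(8,2,0), MCI(1,7,2), AD(0,1,9)
        y, pred = [], []
        for true_c, row in enumerate([(8, 2, 0), (1, 7, 2), (0, 1, 9)]):
            for pred_c, count in enumerate(row):
                y += [true_c] * count
                pred += [pred_c] * count
        proba = np.eye(3)[pred] * 0.9 + 0.05
        rep = evaluate_predictions(np.array(y), proba)
        ad = rep.per_class.loc["AD"]
        assert ad["tp"] == 9 and ad["fp"] == 2 and ad["fn"] == 1
        assert ad["precision"] == pytest.approx(9 / 11)
        assert ad["recall"] == pytest.approx(0.9)
        expected_f1 = 2 * (9 / 11 * 0.9) / (9 / 11 + 0.9)
        assert ad["f1"] == pytest.approx(expected_f1)
        # metric identities
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / rep.n)
        recall_dot_support = sum(
            rep.per_class.loc[c, "recall"] * rep.confusion[i].sum()
            for i, c in enumerate(("CN", "MCI", "AD"))
        )
        assert recall_dot_support == pytest.approx(np.trace(rep.confusion))

    def test_uniform_scores_give_chance_auc(self):
        rng = np.random.default_rng(0)
        n = 3000
        y = np.repeat([0, 1, 2], n // 3)
        proba = rng.uniform(size=(n, 3))
        proba /= proba.sum(axis=1, keepdims=True)
        rep = evaluate_predictions(y, proba)
        for c in ("CN", "MCI", "AD"):
            assert abs(rep.per_class.loc[c, "auc"] - 0.5) < 0.05

    def test_absent_class_auc_undefined_and_excluded(self):
        y = np.repeat([0, 1], 10)  # no AD
        rng = np.random.default_rng(1)
        proba = rng.uniform(size=(20, 3)); proba /= proba.sum(1, keepdims=True)
        rep = evaluate_predictions(y, proba)
        assert "AD" in rep.undefined_auc
        assert np.isnan(rep.per_class.loc["AD", "auc"])
        assert not np.isnan(rep.macro_auc)


class TestEndToEnd:
    def test_planted_cohort_performance(self, planted_run):
        *_, report = planted_run
        assert report.macro_auc >= 0.9
        assert report.accuracy >= 0.8

    def test_baseline_also_learns_planted_signal(self, planted_setup):
        from pathwaynet import train_and_evaluate

        _, dataset, mask_snp, mask_expr = planted_setup
        _, _, rep = train_and_evaluate(dataset, mask_snp, mask_expr, seed=1, baseline=True)
        assert rep.macro_auc > 0.8
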