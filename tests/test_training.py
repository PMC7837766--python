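"""EUD-weighted loss algebra and the training loop."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dvhgru.dvh import OARConfig, default_oar_config
from dvhgru.predictor import ModelSpec, predict_batch
from dvhgru.training import (
    TrainConfig,
    eud_weighted_loss,
    eud_weighted_loss_grad,
    grid_search_k,
    train_oar_model,
    train_previous_baseline,
)

CORD = default_oar_config("spinal_cord")


class TestLossAlgebra:
    def test_zero_at_perfect_prediction(self, rng):
        t = rng.uniform(1, 50, size=(3, 10))
        assert eud_weighted_loss(t, t, 8) == 0.0

    def test_hand_example(self):
        # target {1,2}, predicted {2,2}, k=2: s={1/3,2/3}, f = 1/3
        f = eud_weighted_loss(np.array([2.0, 2.0]), np.array([1.0, 2.0]), 2)
        assert f == pytest.approx(1 / 3, rel=1e-15)

    def test_k1_equals_uniform_mse(self, rng):
        pred = rng.uniform(0, 60, size=(5, 100))
        targ = rng.uniform(0, 60, size=(5, 100))
        f = eud_weighted_loss(pred, targ, 1)
        mse = np.mean((pred - targ) ** 2, axis=1).mean()
        assert f == pytest.approx(mse, rel=1e-14)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            eud_weighted_loss(np.ones(4), np.ones(5), 1)

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            eud_weighted_loss(np.ones(4), np.ones(4), 0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_top_decile_loss_share_non_decreasing_in_k(self, seed):
        rng = np.random.default_rng(seed)
        targ = np.sort(rng.uniform(1, 60, size=100))[::-1]
        pred = targ + rng.normal(0, 2, size=100)
        shares = []
        for k in (1, 2, 4, 8, 15):
            from dvhgru.dvh import sensitivity_weights

            s = sensitivity_weights(targ, k)
            contrib = s * (pred - targ) ** 2
            shares.append(contrib[:10].sum() / contrib.sum())
        assert np.all(np.diff(shares) >= -1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        pred = rng.uniform(1, 10, size=(2, 8))
        targ = rng.uniform(1, 10, size=(2, 8))
        g = eud_weighted_loss_grad(pred, targ, 5)
        eps = 1e-6
        for i in np.ndindex(pred.shape):
            old = pred[i]
            pred[i] = old + eps
            lp = eud_weighted_loss(pred, targ, 5)
            pred[i] = old - eps
            lm = eud_weighted_loss(pred, targ, 5)
            pred[i] = old
            fd = (lp - lm) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5)


FAST_SPEC = ModelSpec(hidden_size=8, dropout_p=0.0, seed=1)


class TestTrainOARModel:
    def test_loss_decreases_and_deterministic(self, noiseless_cohort):
        cfg = TrainConfig(epochs=150, k=1, seed=2)
        m1 = train_oar_model(noiseless_cohort.train_cases, CORD, FAST_SPEC, cfg)
        m2 = train_oar_model(noiseless_cohort.train_cases, CORD, FAST_SPEC, cfg)
        assert m1.metadata["final_loss"] < m1.metadata["first_loss"]
        for a, b in zip(m1.params.flatten(), m2.params.flatten()):
            np.testing.assert_array_equal(a, b)

    def test_noiseless_convergence_and_dvh_recovery(self, noiseless_cohort):
        """On a noiseless cohort the fit approaches the exact mapping."""
        cfg = TrainConfig(epochs=800, k=1, seed=3)
        spec = ModelSpec(hidden_size=16, dropout_p=0.0, seed=3)
        m = train_oar_model(noiseless_cohort.train_cases, CORD, spec, cfg)
        assert m.metadata["final_loss"] < 0.01 * m.metadata["first_loss"]
        preds = predict_batch(
            m, [c.oars["spinal_cord"][0] for c in noiseless_cohort.test_cases]
        )
        for pred, case in zip(preds, noiseless_cohort.test_cases):
            rms = np.sqrt(np.mean((pred.doses - case.oars["spinal_cord"][1].doses) ** 2))
            assert rms < 1.0  # Gy

    def test_dropout_training_still_deterministic(self, small_cohort):
        spec = ModelSpec(hidden_size=6, dropout_p=0.5, seed=4)
        cfg = TrainConfig(epochs=30, k=1, seed=5)
        m1 = train_oar_model(small_cohort.train_cases, CORD, spec, cfg)
        m2 = train_oar_model(small_cohort.train_cases, CORD, spec, cfg)
        for a, b in zip(m1.params.flatten(), m2.params.flatten()):
            np.testing.assert_array_equal(a, b)

    def test_divergence_aborts_with_diagnostic(self, small_cohort):
        # a step this large overflows the squared-error loss at once
        cfg = TrainConfig(epochs=10, k=1, seed=0, learning_rate=1e160)
        with pytest.raises(RuntimeError, match="epoch"):
            train_oar_model(small_cohort.train_cases, CORD, FAST_SPEC, cfg)

    def test_early_stopping_returns_best_validation_params(self, small_cohort):
        cfg = TrainConfig(epochs=120, k=1, seed=6, patience=15)
        m = train_oar_model(
            small_cohort.train_cases[:-3], CORD, FAST_SPEC, cfg,
            val_cases=small_cohort.train_cases[-3:],
        )
        vh = m.metadata["val_history"]
        assert len(vh) <= 120
        # returned parameters correspond to the best recorded validation loss
        from dvhgru.training import _training_arrays, eud_weighted_loss
        from dvhgru import nn

        Xv, Yv = _training_arrays(
            small_cohort.train_cases[-3:], "spinal_cord", FAST_SPEC
        )
        yv, _ = nn.forward(m.params, Xv)
        assert eud_weighted_loss(yv, Yv, 1) == pytest.approx(min(vh), rel=1e-9)

    def test_needs_two_cases(self, small_cohort):
        with pytest.raises(ValueError):
            train_oar_model(small_cohort.train_cases[:1], CORD, FAST_SPEC)


class TestGridSearchK:
    def test_singleton_candidate(self, small_cohort):
        cfg = TrainConfig(epochs=25, seed=1)
        res = grid_search_k(
            small_cohort.train_cases[:-3], CORD, [1], FAST_SPEC, cfg,
            val_cases=small_cohort.train_cases[-3:],
        )
        assert res.selected_k == 1
        assert len(res.table) == 1

    def test_objective_recomputable_from_models(self, small_cohort):
        cfg = TrainConfig(epochs=25, seed=1)
        val = small_cohort.train_cases[-3:]
        res = grid_search_k(
            small_cohort.train_cases[:-3], CORD, [1, 8], FAST_SPEC, cfg, val_cases=val
        )
        from dvhgru.evaluation import mu_sigma, prediction_errors

        for row in res.table:
            m = res.models[row["k"]]
            errs = prediction_errors(
                predict_batch(m, [c.oars["spinal_cord"][0] for c in val]), val, CORD
            )
            mu_e, sd_e = mu_sigma(errs["eud"])
            mu_d, sd_d = mu_sigma(errs["dmax"])
            assert row["objective"] == pytest.approx(
                abs(mu_e) + sd_e + abs(mu_d) + sd_d, rel=1e-12
            )

    def test_empty_candidates_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="empty"):
            grid_search_k(
                small_cohort.train_cases[:-3], CORD, [], FAST_SPEC,
                TrainConfig(epochs=5), val_cases=small_cohort.train_cases[-3:],
            )

    def test_requires_validation_split(self, small_cohort):
        with pytest.raises(ValueError, match="validation"):
            grid_search_k(small_cohort.train_cases, CORD, [1], FAST_SPEC,
                          TrainConfig(epochs=5), val_cases=None)


class TestBaseline:
    def test_baseline_trains_and_predicts_valid_dvhs(self, small_cohort):
        spec = ModelSpec(hidden_size=6, dropout_p=0.0, seed=2)
        cfg = TrainConfig(epochs=30, seed=2)
        bl = train_previous_baseline(small_cohort.train_cases, None, spec, cfg)
        assert bl.trained.spec.num_layers == 3
        assert np.isfinite(bl.trained.metadata["final_loss"])
        preds = bl.predict_cases(small_cohort.test_cases, "spinal_cord")
        for p in preds:
            assert np.all(np.diff(p.doses) <= 1e-12) and np.all(p.doses >= 0)

    def test_baseline_rejects_weighted_loss(self, small_cohort):
        with pytest.raises(ValueError, match="k = 1"):
            train_previous_baseline(
                small_cohort.train_cases, None, FAST_SPEC, TrainConfig(epochs=5, k=8)
            )

    def test_unknown_oar_rejected(self, small_cohort):
        spec = ModelSpec(hidden_size=4, dropout_p=0.0, seed=0)
        bl = train_previous_baseline(
            small_cohort.train_cases, None, spec, TrainConfig(epochs=5)
        )
        with pytest.raises(KeyError):
            bl.predict(small_cohort.test_cases[0].oars["spinal_cord"][0], "liver")
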