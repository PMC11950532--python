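"""Model training: checkpoint selection, transfer/freeze contracts,
learnability on phantoms, and prediction invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xbrainage.models import (CheckpointStore, NetSpec, TrainConfig,
                              n_encoder_params, predict_age,
                              select_best_checkpoint, train_cae,
                              train_regressor, transfer_encoder)


def _store_from_scores(scores):
    store = CheckpointStore(retain=len(scores))
    for i, s in enumerate(scores, start=1):
        store.add(i, s, [np.array([float(i)])])
    return store


class TestCheckpointSelection:
    @pytest.mark.parametrize("scores,window,expected", [
        ([5, 4, 3, 2, 1], 3, 5),   # monotone: last epoch wins
        ([1, 9, 9, 9, 9], 3, 3),   # epoch 1 outside window despite lower score
        ([4, 2, 2, 5], 4, 2),      # tie goes to the earliest epoch
    ])
    def test_window_and_tie_rules(self, scores, window, expected):
        state, epoch = select_best_checkpoint(_store_from_scores(scores), window)
        assert epoch == expected
        assert state[0][0] == float(expected)

    def test_empty_store_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_best_checkpoint(CheckpointStore(retain=3), 3)

    def test_epochs_must_increase(self):
        store = _store_from_scores([1.0, 2.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            store.add(2, 0.5, [np.zeros(1)])

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=60),
           st.integers(1, 30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_selected_epoch_always_inside_window(self, scores, window):
        store = _store_from_scores(scores)
        window = min(window, len(scores))
        _, epoch = select_best_checkpoint(store, window)
        assert len(scores) - window + 1 <= epoch <= len(scores)
        assert store.scores[epoch - 1] == min(store.scores[-window:])


@pytest.fixture(scope="module")
def tiny_spec():
    return NetSpec(input_shape=(8, 8, 8), in_channels=1,
                   encoder_widths=(2, 4), latent_dim=8, head_widths=(4,))


class TestTrainCae:
    def test_zero_volumes_are_trivially_learnable(self, tiny_spec):
        vols = np.zeros((6, 1, 8, 8, 8))
        cfg = TrainConfig(epochs=5, batch_size=4, selection_window=5, seed=0)
        store, log = train_cae(vols, vols[:2], tiny_spec, cfg)
        assert store.scores[-1] <= store.scores[0]
        assert len(store) == 5

    def test_same_seed_reproduces_epoch_losses(self, tiny_spec):
        rng = np.random.default_rng(0)
        vols = rng.normal(size=(6, 1, 8, 8, 8))
        cfg = TrainConfig(epochs=2, batch_size=4, selection_window=2, seed=3)
        _, log1 = train_cae(vols, vols[:1], tiny_spec, cfg)
        _, log2 = train_cae(vols, vols[:1], tiny_spec, cfg)
        assert log1["train_loss"].iloc[0] == log2["train_loss"].iloc[0]
        assert list(log1["val_score"]) == list(log2["val_score"])

    def test_single_validation_volume_is_fine(self, tiny_spec):
        rng = np.random.default_rng(1)
        vols = rng.normal(size=(4, 1, 8, 8, 8))
        cfg = TrainConfig(epochs=3, batch_size=4, selection_window=3, seed=0)
        store, _ = train_cae(vols, vols[:1], tiny_spec, cfg)
        assert len(store.scores) == 3

    def test_shape_mismatch_is_named(self, tiny_spec):
        with pytest.raises(ValueError, match="train_volumes"):
            train_cae(np.zeros((3, 1, 4, 4, 4)), np.zeros((1, 1, 8, 8, 8)),
                      tiny_spec, TrainConfig(epochs=1, selection_window=1))


class TestTransfer:
    def test_encoder_frozen_bit_identical_after_head_training(
            self, trained_small_model):
        spec = trained_small_model["spec"]
        model = trained_small_model["model"]
        n_enc = n_encoder_params(spec)
        for p, original in zip(model.params()[:n_enc],
                               trained_small_model["cae_state"][:n_enc]):
            assert not p.trainable
            np.testing.assert_array_equal(p.value, original)

    def test_trainable_parameters_are_exactly_the_head(self, tiny_spec):
        rng = np.random.default_rng(0)
        from xbrainage.models import build_cae
        cae = build_cae(tiny_spec, seed=1)
        model = transfer_encoder(cae.state_dict(), tiny_spec, seed=2)
        n_enc = n_encoder_params(tiny_spec)
        trainable = [p for p in model.params() if p.trainable]
        assert len(trainable) == len(model.params()) - n_enc

    def test_seed_scopes_head_init_only(self, tiny_spec):
        from xbrainage.models import build_cae
        cae_state = build_cae(tiny_spec, seed=1).state_dict()
        m1 = transfer_encoder(cae_state, tiny_spec, seed=10)
        m2 = transfer_encoder(cae_state, tiny_spec, seed=11)
        n_enc = n_encoder_params(tiny_spec)
        for p1, p2 in zip(m1.params()[:n_enc], m2.params()[:n_enc]):
            np.testing.assert_array_equal(p1.value, p2.value)
        heads_differ = any(
            not np.array_equal(p1.value, p2.value)
            for p1, p2 in zip(m1.params()[n_enc:-1], m2.params()[n_enc:-1]))
        assert heads_differ

    def test_layout_mismatch_is_reported(self, tiny_spec):
        from xbrainage.models import build_cae
        bad = build_cae(tiny_spec, seed=1).state_dict()
        bad[0] = np.zeros((3, 3))
        with pytest.raises(ValueError, match="parameter 0"):
            transfer_encoder(bad, tiny_spec, seed=0)


class TestRegressorLearnability:
    def test_beats_mean_age_baseline_on_strong_signal(self, trained_small_model):
        ages = trained_small_model["ages"]
        val_ages = ages[64:]
        baseline = np.mean(np.abs(val_ages - ages[:56].mean()))
        best = min(trained_small_model["reg_store"].scores)
        assert best < baseline

    def test_shuffled_ages_do_not_beat_baseline(self, trained_small_model,
                                                net_spec_small):
        vols = trained_small_model["volumes"]
        ages = trained_small_model["ages"].copy()
        rng = np.random.default_rng(99)
        shuffled = rng.permutation(ages[:56])
        model = transfer_encoder(trained_small_model["cae_state"],
                                 net_spec_small, seed=31)
        cfg = TrainConfig(epochs=12, batch_size=8, learning_rate=1e-2,
                          selection_window=12, seed=32)
        store, _ = train_regressor(model, vols[:56], shuffled,
                                   vols[64:], ages[64:], net_spec_small, cfg)
        baseline = np.mean(np.abs(ages[64:] - shuffled.mean()))
        assert min(store.scores) > 0.75 * baseline

    def test_same_seed_selects_same_checkpoint(self, trained_small_model,
                                               net_spec_small):
        vols = trained_small_model["volumes"]
        ages = trained_small_model["ages"]
        results = []
        for _ in range(2):
            model = transfer_encoder(trained_small_model["cae_state"],
                                     net_spec_small, seed=41)
            cfg = TrainConfig(epochs=4, batch_size=8, learning_rate=1e-2,
                              selection_window=4, seed=42)
            store, _ = train_regressor(model, vols[:32], ages[:32],
                                       vols[64:], ages[64:],
                                       net_spec_small, cfg)
            state, epoch = select_best_checkpoint(store, 4)
            results.append((epoch, state))
        assert results[0][0] == results[1][0]
        for a, b in zip(results[0][1], results[1][1]):
            np.testing.assert_array_equal(a, b)

    def test_unfrozen_model_is_rejected(self, net_spec_small):
        from xbrainage.models import build_regressor
        model = build_regressor(net_spec_small, seed=0)
        with pytest.raises(ValueError, match="frozen"):
            train_regressor(model, np.zeros((4, 1, 16, 16, 16)), np.zeros(4),
                            np.zeros((1, 1, 16, 16, 16)), np.zeros(1),
                            net_spec_small,
                            TrainConfig(epochs=1, selection_window=1))


class TestPredict:
    def test_duplicates_in_batch_predict_identically(self, trained_small_model):
        model = trained_small_model["model"]
        v = trained_small_model["volumes"][0]
        batch = np.stack([v, v, trained_small_model["volumes"][1]])
        preds = predict_age(model, batch)
        assert preds[0] == preds[1]

    def test_batch_size_does_not_change_predictions(self, trained_small_model):
        model = trained_small_model["model"]
        vols = trained_small_model["volumes"][:8]
        single = predict_age(model, vols[0][None])
        batched = predict_age(model, vols, batch_size=8)
        assert abs(single[0] - batched[0]) < 1e-5

    def test_zero_volume_gives_finite_output(self, trained_small_model):
        pred = predict_age(trained_small_model["model"],
                           np.zeros((1, 1, 16, 16, 16)))
        assert np.isfinite(pred[0])

    def test_wrong_shape_rejected(self, trained_small_model):
        with pytest.raises(ValueError):
            predict_age(trained_small_model["model"], np.zeros((2, 3)))
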