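"""Network assembly, feature fusion, training behaviour, checkpoints."""

import numpy as np
import pytest
from sklearn.base import clone

from ppgrehab.model import (
    ModelConfig,
    Network,
    PpgStageClassifier,
    classify,
    load_model,
    mcnn_extract,
    save_model,
    train,
)

TINY = ModelConfig(
    window_len=40,
    shallow_branch=(7, 1, 2),
    deep_branch=(3, 2, 4),
    pool_width=2,
    lstm_hidden=6,
    lstm_layers=1,
    attention_dim=4,
    fc_sizes=(8,),
    dropout_p=0.0,
    epochs=8,
    batch_size=8,
    learning_rate=1e-2,
    seed=0,
)


def toy_windows(n_per_class=12, window_len=40, seed=0):
    """Three sine-shaped classes distinguishable by frequency."""
    rng = np.random.default_rng(seed)
    t = np.arange(window_len)
    X, y = [], []
    for ci, freq in enumerate((0.05, 0.12, 0.25)):
        for _ in range(n_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            w = np.sin(2 * np.pi * freq * t + phase)
            X.append(np.stack([w, w * 0.8, w * 0.6]) +
                     0.05 * rng.standard_normal((3, window_len)))
            y.append(["V", "VI", "VII"][ci])
    return np.asarray(X), np.asarray(y)


class TestFeatureExtraction:
    def test_feature_axis_size(self, rng):
        net = Network(TINY, "mcnn_lstm_attention", rng)
        x = rng.standard_normal((2, 3, 40))
        feats = net.extract_features(x)
        assert feats.shape == (2, net.t_common, 3 * (2 + 4))

    def test_zero_input_gives_zero_features(self, rng):
        net = Network(TINY, "mcnn_lstm_attention", rng)
        feats = net.extract_features(np.zeros((1, 3, 40)))
        np.testing.assert_allclose(feats, 0.0)

    def test_wavelength_permutation_permutes_feature_blocks(self, rng):
        net = Network(TINY, "mcnn_lstm_attention", rng)
        x = rng.standard_normal((1, 3, 40))
        perm = [2, 0, 1]
        f_orig = net.extract_features(x)
        f_perm = net.extract_features(x[:, perm, :])
        fpw = 2 + 4  # features per wavelength
        for dst, src in enumerate(perm):
            np.testing.assert_allclose(
                f_perm[:, :, dst * fpw:(dst + 1) * fpw],
                f_orig[:, :, src * fpw:(src + 1) * fpw],
            )

    def test_window_length_mismatch_raises(self, rng):
        net = Network(TINY, "mcnn_lstm", rng)
        with pytest.raises(ValueError):
            net.extract_features(np.zeros((1, 3, 30)))

    def test_mcnn_extract_function(self):
        feats = mcnn_extract(np.zeros((2, 3, 40)), TINY)
        assert feats.ndim == 3 and feats.shape[0] == 2


class TestConfigInvariants:
    @pytest.mark.parametrize("kwargs", [
        {"shallow_branch": (3, 1, 2), "deep_branch": (5, 2, 4)},  # kernel order
        {"shallow_branch": (7, 3, 2), "deep_branch": (5, 2, 4)},  # layer order
        {"dropout_p": 1.0},
        {"n_classes": 1},
    ])
    def test_invalid_configs_raise(self, kwargs):
        with pytest.raises(ValueError):
            TINY.with_(**kwargs).validate()

    def test_single_branch_has_fewer_parameters(self, rng):
        full = Network(TINY, "mcnn_lstm_attention", np.random.default_rng(0))
        ablated = Network(TINY, "cnn_lstm_attention", np.random.default_rng(0))
        assert ablated.n_params() < full.n_params()


class TestClassify:
    def test_probabilities_sum_to_one(self, rng):
        net = Network(TINY, "mcnn_lstm_attention", rng)
        p = net.predict_proba(rng.standard_normal((4, 3, 40)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_untrained_model_uniform_on_zero_input(self, rng):
        net = Network(TINY, "mcnn_lstm_attention", rng)
        p = net.predict_proba(np.zeros((1, 3, 40)))
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-9)

    def test_attention_weights_normalized_every_pass(self, rng):
        net = Network(TINY, "mcnn_lstm_attention", rng)
        net.forward(rng.standard_normal((5, 3, 40)))
        np.testing.assert_allclose(net.attention.last_alpha.sum(axis=1), 1.0,
                                   atol=1e-6)


class TestTraining:
    def test_first_epoch_loss_near_log_k(self):
        X, y = toy_windows()
        model = train(X, y, TINY.with_(epochs=1), "mcnn_lstm_attention")
        assert abs(model.history["train_loss"][0] - np.log(3)) <= 0.25

    def test_seeded_determinism(self):
        X, y = toy_windows()
        cfg = TINY.with_(epochs=3, dropout_p=0.2)
        a = train(X, y, cfg, "mcnn_lstm_attention")
        b = train(X, y, cfg, "mcnn_lstm_attention")
        assert a.history["train_loss"] == b.history["train_loss"]

    def test_single_class_refused(self):
        X, y = toy_windows()
        with pytest.raises(ValueError, match="classes"):
            train(X, np.full(len(X), "V"), TINY, "cnn_lstm")

    def test_learns_separable_toy_problem(self):
        X, y = toy_windows()
        model = train(X, y, TINY.with_(epochs=20), "mcnn_lstm_attention",
                      validation=(X, y))
        assert model.history["val_acc"][-1] >= 0.9

    def test_classify_wrapper_single_window(self):
        X, y = toy_windows(n_per_class=4)
        model = train(X, y, TINY.with_(epochs=1), "mcnn_lstm")
        p = classify(X[0], model)
        assert p.shape == (3,)
        assert p.sum() == pytest.approx(1.0)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        X, y = toy_windows(n_per_class=4)
        model = train(X, y, TINY.with_(epochs=2), "mcnn_lstm_attention")
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_allclose(loaded.predict_proba(X),
                                   model.predict_proba(X), atol=1e-12)
        assert list(loaded.classes) == list(model.classes)


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        est = PpgStageClassifier(architecture="cnn_lstm", epochs=2)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_predict(self):
        X, y = toy_windows()
        est = PpgStageClassifier(
            architecture="mcnn_lstm_attention",
            shallow_branch=(7, 1, 2), deep_branch=(3, 2, 4), pool_width=2,
            lstm_hidden=6, lstm_layers=1, attention_dim=4, fc_sizes=(8,),
            dropout_p=0.0, epochs=20, batch_size=8, learning_rate=1e-2, seed=0,
        )
        est.fit(X, y)
        assert est.score(X, y) >= 0.9
        assert set(est.predict(X)) <= {"V", "VI", "VII"}
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            PpgStageClassifier().predict_proba(np.zeros((1, 3, 40)))
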