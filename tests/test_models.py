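import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from stresspipe import models as M
from stresspipe import nn


class TestParameterCounts:
    # Published totals for the single-recurrent-layer stacks; exact under
    # univariate input and the double-bias GRU.
    @pytest.mark.parametrize(
        "name,expected",
        [("CNN-RNN", 12_673), ("CNN-LSTM", 49_729), ("CNN-GRU", 37_569)],
    )
    def test_published_totals(self, name, expected):
        assert M.count_parameters(M.ModelSpec(name)) == expected

    @pytest.mark.parametrize("name", M.MODEL_NAMES)
    @pytest.mark.parametrize("window_length", [64, 128, 256])
    def test_closed_form_matches_built_model(self, name, window_length):
        spec = M.ModelSpec(name)
        model = M.build_model(spec, window_length, seed=0)
        assert model.n_params() == M.count_parameters(spec)

    def test_window_length_never_changes_count(self):
        spec = M.ModelSpec("CBGG")
        counts = {M.build_model(spec, L, seed=0).n_params() for L in (64, 128, 256)}
        assert len(counts) == 1

    def test_single_bias_gru_variant(self):
        # 256 + 3*64*(128+64+1) + 65
        assert M.count_parameters(M.ModelSpec("CNN-GRU", gru_variant="single_bias")) == 37_377

    def test_dense_component(self):
        # Dense(1) on 16 inputs contributes 17; CBGG ends in GRU(16) -> Dense
        with_dense = M.count_parameters(M.ModelSpec("CBGG"))
        model = M.build_model(M.ModelSpec("CBGG"), 64, seed=0)
        assert model.layers[-1].n_params() == 17
        assert with_dense - sum(l.n_params() for l in model.layers[:-1]) == 17


class TestBuildModel:
    def test_cbgg_layer_sequence(self):
        model = M.build_model(M.ModelSpec("CBGG"), 128, seed=0)
        kinds = [type(layer).__name__ for layer in model.layers]
        assert kinds == [
            "PointwiseConv1D", "MaxPool1D", "Bidirectional", "GRU", "GRU",
            "Dropout", "Dense",
        ]
        assert model.layers[3].units == 32
        assert model.layers[4].units == 16

    def test_intermediate_layers_return_sequences(self):
        model = M.build_model(M.ModelSpec("CBLL"), 128, seed=0)
        assert model.layers[2].return_sequences is True  # BiLSTM
        assert model.layers[3].return_sequences is True  # LSTM(32)
        assert model.layers[4].return_sequences is False  # LSTM(16) -> state

    def test_output_single_probability(self):
        model = M.build_model(M.ModelSpec("CNN-LSTM"), 32, seed=0)
        out = model.forward(np.zeros((5, 32, 1)))
        assert out.shape == (5, 1)
        assert np.all((out > 0) & (out < 1))

    def test_softmax_normalises_filters(self):
        model = M.build_model(M.ModelSpec("CNN-RNN"), 16, seed=0)
        conv_out = model.layers[0].forward(np.random.default_rng(0).normal(size=(2, 16, 1)))
        assert conv_out.shape == (2, 16, 128)
        assert np.allclose(conv_out.sum(axis=-1), 1.0, atol=1e-5)

    def test_unknown_name_raises(self):
        with pytest.raises(M.UnknownModelError):
            M.ModelSpec("CNN-TRANSFORMER")

    def test_bad_window_length_raises(self):
        with pytest.raises(ValueError):
            M.build_model(M.ModelSpec("CBGG"), 0)


class TestTrain:
    def test_separable_toy_reaches_90(self, separable_windows):
        X, y = separable_windows
        # independent oracle: the task is linearly separable for logistic
        # regression on window means, which reaches >= 90%
        oracle = LogisticRegression().fit(X.mean(axis=1), y)
        assert oracle.score(X.mean(axis=1), y) >= 0.9

        model = M.build_model(M.ModelSpec("CNN-GRU"), X.shape[1], seed=0)
        model, trace = M.train(
            model, (X, y), None, M.TrainConfig(epochs=20, batch_size=50, seed=0)
        )
        assert trace.train_acc[-1] >= 0.9

    def test_loss_mostly_non_increasing(self, separable_windows):
        X, y = separable_windows
        model = M.build_model(M.ModelSpec("CNN-RNN"), X.shape[1], seed=1)
        _, trace = M.train(model, (X, y), None, M.TrainConfig(epochs=20, batch_size=50, seed=1))
        drops = np.diff(trace.train_loss) <= 1e-9
        assert np.mean(drops) >= 0.8

    def test_deterministic_trace(self, separable_windows):
        X, y = separable_windows
        config = M.TrainConfig(epochs=3, batch_size=50, seed=4)
        traces = []
        for _ in range(2):
            model = M.build_model(M.ModelSpec("CNN-RNN"), X.shape[1], seed=4)
            _, trace = M.train(model, (X, y), (X, y), config)
            traces.append(trace)
        assert traces[0].train_loss == traces[1].train_loss
        assert traces[0].val_acc == traces[1].val_acc

    def test_single_class_raises(self):
        X = np.zeros((20, 8, 1))
        y = np.ones(20)
        model = M.build_model(M.ModelSpec("CNN-RNN"), 8, seed=0)
        with pytest.raises(M.SingleClassError):
            M.train(model, (X, y), None, M.TrainConfig(epochs=1, seed=0))

    def test_validation_trace_recorded(self, separable_windows):
        X, y = separable_windows
        model = M.build_model(M.ModelSpec("CNN-RNN"), X.shape[1], seed=0)
        _, trace = M.train(model, (X, y), (X[:40], y[:40]),
                           M.TrainConfig(epochs=4, batch_size=50, seed=0))
        assert trace.n_epochs() == 4
        assert len(trace.val_loss) == len(trace.val_acc) == 4


@pytest.fixture(scope="module")
def fitted(separable_windows):
    X, y = separable_windows
    model = M.build_model(M.ModelSpec("CNN-RNN"), X.shape[1], seed=0)
    model, _ = M.train(model, (X, y), None, M.TrainConfig(epochs=5, batch_size=50, seed=0))
    return model, X, y


class TestPredict:
    def test_probabilities_in_open_interval(self, fitted):
        model, X, _ = fitted
        probs, _ = M.predict(model, X)
        assert np.all((probs > 0) & (probs < 1))

    def test_tie_maps_to_stress(self):
        # the >= rule: probability exactly at the threshold labels as 1
        model = M.build_model(M.ModelSpec("CNN-RNN"), 8, seed=0)
        model.fitted = True
        probs, labels = M.predict(model, np.zeros((3, 8, 1)), threshold=0.5)
        expected = (probs >= 0.5).astype(int)
        assert np.array_equal(labels, expected)

    def test_extreme_thresholds(self, fitted):
        model, X, _ = fitted
        _, all_one = M.predict(model, X, threshold=1e-9)
        _, all_zero = M.predict(model, X, threshold=1.0 - 1e-9)
        assert np.all(all_one == 1)
        assert np.all(all_zero == 0)

    def test_order_permutation_invariance(self, fitted):
        model, X, _ = fitted
        perm = np.random.default_rng(0).permutation(len(X))
        probs, _ = M.predict(model, X)
        probs_perm, _ = M.predict(model, X[perm])
        assert np.allclose(probs[perm], probs_perm, atol=1e-6)

    def test_unfitted_model_raises(self):
        model = M.build_model(M.ModelSpec("CNN-RNN"), 8, seed=0)
        with pytest.raises(RuntimeError):
            M.predict(model, np.zeros((2, 8, 1)))


class TestSaveLoad:
    def test_round_trip_preserves_predictions(self, tmp_path, separable_windows):
        X, y = separable_windows
        model = M.build_model(M.ModelSpec("CNN-GRU"), X.shape[1], seed=0)
        model, _ = M.train(model, (X, y), None, M.TrainConfig(epochs=2, batch_size=50, seed=0))
        model.save(tmp_path / "model.npz")
        loaded = M.Model.load(tmp_path / "model.npz")
        probs, _ = M.predict(model, X)
        probs_loaded, _ = M.predict(loaded, X)
        assert np.allclose(probs, probs_loaded)


class TestGradients:
    @pytest.mark.parametrize("name", M.MODEL_NAMES)
    def test_backward_matches_finite_differences(self, name):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((3, 6, 1))
        y = np.array([0.0, 1.0, 1.0])
        model = M.build_model(M.ModelSpec(name), 6, seed=3, dtype=np.float64)
        p = model.forward(X).ravel()
        model.zero_grads()
        model.backward(((p - y) / len(y))[:, None])
        checked = 0
        for layer in model.layers:
            subs = [layer.fwd, layer.bwd] if isinstance(layer, nn.Bidirectional) else [layer]
            for sub in subs:
                for key, param in sub.params.items():
                    flat = param.ravel()
                    for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                        eps, old = 1e-6, flat[i]
                        flat[i] = old + eps
                        lp = nn.bce_loss(model.forward(X).ravel(), y)
                        flat[i] = old - eps
                        lm = nn.bce_loss(model.forward(X).ravel(), y)
                        flat[i] = old
                        numeric = (lp - lm) / (2 * eps)
                        analytic = sub.grads[key].ravel()[i]
                        assert abs(numeric - analytic) < 1e-7, (key, numeric, analytic)
                        checked += 1
        assert checked > 0
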