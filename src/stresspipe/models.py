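"""The six hybrid CNN/recurrent architectures: build, count, train, predict.

Every architecture shares the same front end — a kernel-size-1 Conv1D with
128 filters whose outputs are softmax-normalised per time step, followed by a
pool-size-1 max pool kept for architecture parity — and ends in dropout (0.2)
plus a single sigmoid unit.  The CB** variants stack BiLSTM(64) -> X(32) ->
X(16); the CNN-X variants use a single X(64).  Inputs are univariate windows
shaped (batch, window_length, 1).

``count_parameters`` does closed-form per-layer accounting, independent of
the built network, and must agree with the handle's own parameter count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "ConvergenceTrace",
    "Model",
    "MODEL_NAMES",
    "build_model",
    "count_parameters",
    "train",
    "predict",
    "UnknownModelError",
    "SingleClassError",
]

MODEL_NAMES = ("CBGG", "CBLL", "CBRR", "CNN-RNN", "CNN-LSTM", "CNN-GRU")

_RECURRENT_STACKS = {
    "CBGG": [("bilstm", 64), ("gru", 32), ("gru", 16)],
    "CBLL": [("bilstm", 64), ("lstm", 32), ("lstm", 16)],
    "CBRR": [("bilstm", 64), ("rnn", 32), ("rnn", 16)],
    "CNN-RNN": [("rnn", 64)],
    "CNN-LSTM": [("lstm", 64)],
    "CNN-GRU": [("gru", 64)],
}


class UnknownModelError(ValueError):
    """Model name is not one of the six architectures."""


class SingleClassError(ValueError):
    """Training data contains only one class."""


@dataclass(frozen=True)
class ModelSpec:
    """Named layer stack with its hyperparameters.

    ``gru_variant`` selects the GRU bias form; the double-bias (reset-after)
    form is the default and the one whose closed-form accounting matches the
    published CNN-GRU total.  ``conv_activation`` defaults to the literal
    softmax-over-filters; ``relu`` is an ablation escape hatch.
    """

    name: str
    conv_filters: int = 128
    dropout_rate: float = 0.2
    gru_variant: str = "double_bias"
    conv_activation: str = "softmax"

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise UnknownModelError(
                f"unknown model {self.name!r}; expected one of {MODEL_NAMES}"
            )
        if self.gru_variant not in ("double_bias", "single_bias"):
            raise ValueError(f"unknown gru_variant {self.gru_variant!r}")

    def layer_descriptors(self) -> list[tuple]:
        """Ordered (kind, arg) descriptors shared by build and count."""
        stack: list[tuple] = [
            ("conv", self.conv_filters),
            ("pool", 1),
        ]
        stack.extend(_RECURRENT_STACKS[self.name])
        stack.append(("dropout", self.dropout_rate))
        stack.append(("dense", 1))
        return stack


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "binary_crossentropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 50
    seed: int = 0
    classification_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if not 0.0 < self.classification_threshold < 1.0:
            raise ValueError(
                f"classification_threshold must be in (0, 1), got "
                f"{self.classification_threshold}"
            )
        if self.loss != "binary_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class ConvergenceTrace:
    """Per-epoch train/validation loss and accuracy."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def n_epochs(self) -> int:
        return len(self.train_loss)


class Model:
    """A built layer stack plus bookkeeping; produced by ``build_model``."""

    def __init__(self, spec: ModelSpec, window_length: int, layers: list[nn.Layer],
                 dtype=np.float32):
        self.spec = spec
        self.window_length = window_length
        self.layers = layers
        self.dtype = dtype
        self.fitted = False

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dz: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dz = layer.backward(dz)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = [
            self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out).ravel()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, nn.Bidirectional):
                for k, v in layer.fwd.params.items():
                    arrays[f"{i}/fwd/{k}"] = v
                for k, v in layer.bwd.params.items():
                    arrays[f"{i}/bwd/{k}"] = v
            else:
                for k, v in layer.params.items():
                    arrays[f"{i}/{k}"] = v
        np.savez(path, **arrays)
        meta = {
            "spec": self.spec.__dict__,
            "window_length": self.window_length,
            "fitted": self.fitted,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = build_model(ModelSpec(**meta["spec"]), meta["window_length"], seed=0)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            for i, layer in enumerate(model.layers):
                if isinstance(layer, nn.Bidirectional):
                    for k in layer.fwd.params:
                        layer.fwd.params[k][...] = data[f"{i}/fwd/{k}"]
                    for k in layer.bwd.params:
                        layer.bwd.params[k][...] = data[f"{i}/bwd/{k}"]
                else:
                    for k in layer.params:
                        layer.params[k][...] = data[f"{i}/{k}"]
        model.fitted = meta["fitted"]
        return model


def build_model(
    spec: ModelSpec, window_length: int, seed: int = 0, dtype=np.float32
) -> Model:
    """Instantiate a trainable network for (window_length x 1) inputs.

    All recurrent layers except the last return full sequences; the last
    returns its final state, which feeds dropout and the sigmoid unit.
    Weights default to float32 (ample for gradient training and roughly twice
    as fast on CPU); pass ``dtype=np.float64`` for e.g. gradient checking.
    """
    if window_length < 1:
        raise ValueError(f"window_length must be >= 1, got {window_length}")
    descriptors = spec.layer_descriptors()
    recurrent_kinds = {"rnn", "lstm", "gru", "bilstm"}
    last_recurrent = max(i for i, (kind, _) in enumerate(descriptors) if kind in recurrent_kinds)

    seq = np.random.SeedSequence([seed, 0x5EED])
    rngs = [np.random.default_rng(s) for s in seq.spawn(len(descriptors) + 1)]

    layers: list[nn.Layer] = []
    in_features = 1
    for i, (kind, arg) in enumerate(descriptors):
        rng = rngs[i]
        ret_seq = i != last_recurrent
        if kind == "conv":
            layers.append(
                nn.PointwiseConv1D(
                    in_features, arg, activation=spec.conv_activation, rng=rng, dtype=dtype
                )
            )
            in_features = arg
        elif kind == "pool":
            layers.append(nn.MaxPool1D(arg))
        elif kind == "rnn":
            layers.append(nn.SimpleRNN(in_features, arg, return_sequences=ret_seq, rng=rng, dtype=dtype))
            in_features = arg
        elif kind == "lstm":
            layers.append(nn.LSTM(in_features, arg, return_sequences=ret_seq, rng=rng, dtype=dtype))
            in_features = arg
        elif kind == "gru":
            layers.append(
                nn.GRU(
                    in_features,
                    arg,
                    return_sequences=ret_seq,
                    double_bias=spec.gru_variant == "double_bias",
                    rng=rng,
                    dtype=dtype,
                )
            )
            in_features = arg
        elif kind == "bilstm":
            fwd = nn.LSTM(in_features, arg, return_sequences=ret_seq, rng=rng, dtype=dtype)
            bwd = nn.LSTM(in_features, arg, return_sequences=ret_seq, rng=rngs[-1], dtype=dtype)
            layers.append(nn.Bidirectional(fwd, bwd))
            in_features = 2 * arg
        elif kind == "dropout":
            layers.append(nn.Dropout(arg, rng=rng))
        elif kind == "dense":
            layers.append(nn.Dense(in_features, arg, activation="sigmoid", rng=rng, dtype=dtype))
            in_features = arg
        else:  # pragma: no cover - descriptors are generated above
            raise ValueError(f"unknown layer kind {kind!r}")
    return Model(spec, window_length, layers, dtype=dtype)


def count_parameters(spec: ModelSpec) -> int:
    """Closed-form trainable-parameter total, summed layer by layer.

    Conv1D (kernel 1, d inputs, F filters): F*d + F.  Simple RNN u units on d
    inputs: u(d+u+1).  LSTM: 4u(d+u+1).  GRU: 3u(d+u+2) double-bias,
    3u(d+u+1) single-bias.  BiLSTM: twice the LSTM count.  Dense(1): d+1.
    Pooling and dropout contribute nothing.
    """
    total = 0
    d = 1
    for kind, arg in spec.layer_descriptors():
        if kind == "conv":
            total += arg * d + arg
            d = arg
        elif kind in ("pool", "dropout"):
            continue
        elif kind == "rnn":
            total += arg * (d + arg + 1)
            d = arg
        elif kind == "lstm":
            total += 4 * arg * (d + arg + 1)
            d = arg
        elif kind == "gru":
            bias_terms = 2 if spec.gru_variant == "double_bias" else 1
            total += 3 * arg * (d + arg + bias_terms)
            d = arg
        elif kind == "bilstm":
            total += 2 * 4 * arg * (d + arg + 1)
            d = 2 * arg
        elif kind == "dense":
            total += d * arg + arg
            d = arg
        else:  # pragma: no cover
            raise ValueError(f"unknown layer kind {kind!r}")
    return total


def _check_binary(y: np.ndarray, what: str) -> None:
    classes = np.unique(y)
    if classes.size < 2:
        raise SingleClassError(f"{what} contains a single class: {classes.tolist()}")


def _eval_on(model: Model, X: np.ndarray, y: np.ndarray, batch_size: int = 512) -> tuple[float, float]:
    p = model.predict_proba(X, batch_size=batch_size)
    return nn.bce_loss(p, y), float(np.mean((p >= 0.5) == y))


def train(
    model: Model,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None = None,
    config: TrainConfig | None = None,
) -> tuple[Model, ConvergenceTrace]:
    """Fit with Adam on binary cross-entropy, recording a convergence trace.

    Deterministic for a fixed seed on a fixed BLAS configuration: shuffling
    and dropout draw from generators derived from ``config.seed``.
    """
    config = config or TrainConfig()
    X, y = train_data
    X = np.asarray(X, dtype=model.dtype)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 3:
        raise ValueError(f"expected (n, window, 1) inputs, got shape {X.shape}")
    if len(X) == 0:
        raise ValueError("empty training set")
    _check_binary(y, "training set")

    seq = np.random.SeedSequence([config.seed, 0x7A1])
    shuffle_rng, dropout_rng = (np.random.default_rng(s) for s in seq.spawn(2))
    for layer in model.layers:
        if isinstance(layer, nn.Dropout):
            layer.rng = dropout_rng

    optimizer = nn.Adam(model.layers, lr=config.learning_rate)
    trace = ConvergenceTrace()
    n = len(X)
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            p = model.forward(xb, training=True).ravel()
            loss = nn.bce_loss(p, yb)
            if not np.isfinite(loss):
                raise nn.DivergenceError(f"non-finite loss at step {optimizer.t}")
            epoch_loss += loss * len(idx)
            epoch_correct += float(np.sum((p >= 0.5) == yb))
            dz = ((p - yb) / len(idx))[:, None]
            model.zero_grads()
            model.backward(dz)
            optimizer.step()
        trace.train_loss.append(epoch_loss / n)
        trace.train_acc.append(epoch_correct / n)
        if val_data is not None:
            vl, va = _eval_on(model, np.asarray(val_data[0]), np.asarray(val_data[1]).ravel())
            trace.val_loss.append(vl)
            trace.val_acc.append(va)
    model.fitted = True
    return model, trace


def predict(
    model: Model, X: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and thresholded labels; probability >= threshold -> 1."""
    if not model.fitted:
        raise RuntimeError("model has not been trained; call train() first")
    p = model.predict_proba(np.asarray(X, dtype=model.dtype))
    return p, (p >= threshold).astype(np.int64)
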