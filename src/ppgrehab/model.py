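"""MCNN-LSTM-Attention stroke-stage classifier and its ablations.

Architecture: each wavelength's preprocessed window passes through two
parallel 1-D convolutional branches — a *shallow* branch with a large
kernel (wide receptive field, few layers) capturing beat shape, and a
*deep* branch with a small kernel and more layers capturing fine
structure.  Branch weights are shared across wavelengths (so permuting
the wavelength inputs permutes the corresponding feature blocks).  The
branch outputs are max-pooled onto a common time axis, concatenated along
the feature axis per wavelength and across wavelengths, fed to stacked
LSTMs, pooled by additive attention (or the last hidden state when the
attention module is ablated), and classified through fully connected
layers with softmax output.

Four variants are supported, differing in whether the shallow branch and
the attention module are present:

========================  ==============  =========
architecture              shallow branch  attention
========================  ==============  =========
``cnn_lstm``              no              no
``cnn_lstm_attention``    no              yes
``mcnn_lstm``             yes             no
``mcnn_lstm_attention``   yes             yes
========================  ==============  =========
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn import (
    Adam,
    AdaptiveMaxPool1D,
    AttentionPool,
    Conv1D,
    Dense,
    Dropout,
    LSTM,
    MaxPool1D,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "ARCHITECTURES",
    "ModelConfig",
    "Network",
    "TrainedModel",
    "train",
    "classify",
    "mcnn_extract",
    "PpgStageClassifier",
]

ARCHITECTURES = ("cnn_lstm", "cnn_lstm_attention", "mcnn_lstm", "mcnn_lstm_attention")


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural and training hyperparameter of the network.

    Branch tuples are (kernel_len, n_layers, n_filters).  The shallow
    branch must have the larger kernel and fewer layers than the deep one.
    """

    window_len: int = 500
    n_channels: int = 3
    shallow_branch: tuple[int, int, int] = (21, 2, 16)
    deep_branch: tuple[int, int, int] = (5, 4, 32)
    pool_width: int = 2
    lstm_hidden: int = 64
    lstm_layers: int = 2
    attention_dim: int = 64
    fc_sizes: tuple[int, ...] = (64,)
    dropout_p: float = 0.5
    n_classes: int = 3
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        sk, sl, _ = self.shallow_branch
        dk, dl, _ = self.deep_branch
        if not sk > dk:
            raise ValueError("shallow branch kernel must exceed deep branch kernel")
        if not sl < dl:
            raise ValueError("shallow branch must have fewer layers than deep branch")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.window_len < max(sk, dk):
            raise ValueError("window_len shorter than the largest kernel")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shallow_branch"] = list(self.shallow_branch)
        d["deep_branch"] = list(self.deep_branch)
        d["fc_sizes"] = list(self.fc_sizes)
        return d

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


def _branch_out_len(window_len: int, kernel: int, n_layers: int, pool: int) -> int:
    t = window_len
    for _ in range(n_layers):
        t = (t - kernel + 1) // pool
        if t < 1:
            raise ValueError("branch arithmetic collapses the time axis to zero")
    return t


class _Branch:
    """Stacked Conv1D + ReLU + MaxPool ending in an adaptive pool that
    aligns the branch onto the network's common time axis."""

    def __init__(self, kernel: int, n_layers: int, n_filters: int, pool: int,
                 out_len: int, rng: np.random.Generator) -> None:
        self.layers = []
        c_in = 1
        for _ in range(n_layers):
            self.layers += [Conv1D(c_in, n_filters, kernel, rng), ReLU(),
                            MaxPool1D(pool)]
            c_in = n_filters
        self.layers.append(AdaptiveMaxPool1D(out_len))
        self.n_filters = n_filters

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Network:
    """Forward/backward graph for one architecture variant."""

    def __init__(self, config: ModelConfig, architecture: str,
                 rng: np.random.Generator) -> None:
        if architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {architecture!r}")
        config.validate()
        self.config = config
        self.architecture = architecture
        self.has_shallow = architecture.startswith("mcnn")
        self.has_attention = architecture.endswith("_attention")

        branch_specs = []
        if self.has_shallow:
            branch_specs.append(config.shallow_branch)
        branch_specs.append(config.deep_branch)
        lens = [_branch_out_len(config.window_len, k, l, config.pool_width)
                for (k, l, _) in branch_specs]
        self.t_common = min(lens)
        self.branches = [
            _Branch(k, l, f, config.pool_width, self.t_common, rng)
            for (k, l, f) in branch_specs
        ]
        feat_per_wav = sum(b.n_filters for b in self.branches)
        d_in = config.n_channels * feat_per_wav
        self.lstms = []
        for i in range(config.lstm_layers):
            self.lstms.append(LSTM(d_in if i == 0 else config.lstm_hidden,
                                   config.lstm_hidden, rng))
        self.attention = (AttentionPool(config.lstm_hidden, config.attention_dim, rng)
                          if self.has_attention else None)
        self.head = []
        d = config.lstm_hidden
        for size in config.fc_sizes:
            self.head += [Dense(d, size, rng), ReLU(),
                          Dropout(config.dropout_p, rng)]
            d = size
        self.head.append(Dense(d, config.n_classes, rng))

    # -- plumbing -----------------------------------------------------------
    def _all_layers(self):
        for b in self.branches:
            yield from b.layers
        yield from self.lstms
        if self.attention is not None:
            yield self.attention
        yield from self.head

    def set_training(self, training: bool) -> None:
        for layer in self._all_layers():
            layer.training = training

    def zero_grad(self) -> None:
        for layer in self._all_layers():
            layer.zero_grad()

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self._all_layers())

    # -- forward ------------------------------------------------------------
    def extract_features(self, x: np.ndarray) -> np.ndarray:
        """Fused (batch, time, features) sequence fed to the LSTM.

        Feature ordering is wavelength-major: for wavelength w the shallow
        block precedes the deep block.
        """
        B, C, T = x.shape
        if C != self.config.n_channels:
            raise ValueError(f"expected {self.config.n_channels} channels, got {C}")
        if T != self.config.window_len:
            raise ValueError(
                f"window length {T} does not match config {self.config.window_len}"
            )
        xw = x.reshape(B * C, 1, T)
        outs = [b.forward(xw) for b in self.branches]
        if len({o.shape[2] for o in outs}) != 1:
            raise RuntimeError("branch time axes misaligned after pooling")
        self._feat_sizes = [o.shape[1] for o in outs]
        cat = np.concatenate(outs, axis=1)           # (B*C, F, Tc)
        self._cat_shape = cat.shape
        feats = cat.reshape(B, C * cat.shape[1], self.t_common)
        return feats.transpose(0, 2, 1)              # (B, Tc, C*F)

    def _features_backward(self, grad: np.ndarray) -> None:
        B = grad.shape[0]
        g = grad.transpose(0, 2, 1).reshape(self._cat_shape)
        offset = 0
        for b, f in zip(self.branches, self._feat_sizes):
            b.backward(g[:, offset:offset + f, :])
            offset += f

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch of windows (batch, channels, window_len)."""
        self.set_training(training)
        seq = self.extract_features(x)
        for lstm in self.lstms:
            seq = lstm.forward(seq)
        if self.attention is not None:
            ctx = self.attention.forward(seq)
        else:
            self._seq_shape = seq.shape
            ctx = seq[:, -1, :]
        z = ctx
        for layer in self.head:
            z = layer.forward(z)
        return z

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.head):
            g = layer.backward(g)
        if self.attention is not None:
            g = self.attention.backward(g)
        else:
            gs = np.zeros(self._seq_shape)
            gs[:, -1, :] = g
            g = gs
        for lstm in reversed(self.lstms):
            g = lstm.backward(g)
        self._features_backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False), axis=1)


def mcnn_extract(windows: np.ndarray, config: ModelConfig,
                 architecture: str = "mcnn_lstm_attention",
                 network: Network | None = None) -> np.ndarray:
    """Fused multi-branch feature sequence for a batch of windows."""
    net = network or Network(config, architecture,
                             np.random.default_rng(config.seed))
    return net.extract_features(np.asarray(windows, dtype=float))


@dataclass
class TrainedModel:
    """A trained network plus the label vocabulary and provenance."""

    network: Network
    classes: np.ndarray
    config: ModelConfig
    architecture: str
    history: dict = field(default_factory=dict)

    def predict_proba(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = _as_batch(windows, self.config)
        out = [self.network.predict_proba(x[i:i + batch_size])
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out) if out else np.zeros((0, len(self.classes)))

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(windows), axis=1)]


def _as_batch(windows: np.ndarray, config: ModelConfig) -> np.ndarray:
    x = np.asarray(windows, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1] != config.n_channels:
        raise ValueError("windows must be (n, n_channels, window_len)")
    if x.shape[2] != config.window_len:
        raise ValueError(
            f"window length {x.shape[2]} does not match config {config.window_len}"
        )
    return x


def _encode_labels(y, classes: np.ndarray) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    return np.asarray([lookup[v] for v in y])


def train(
    windows: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig,
    architecture: str = "mcnn_lstm_attention",
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModel:
    """Train one network by mini-batch Adam on softmax cross-entropy.

    Fully deterministic given ``config.seed``: initialization, shuffling
    and dropout all draw from one seeded generator.  Records per-epoch
    train (and, when given, validation) loss and accuracy.
    """
    config.validate()
    x = _as_batch(windows, config)
    classes = np.unique(np.asarray(labels))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes in the labels")
    if len(classes) != config.n_classes:
        config = config.with_(n_classes=len(classes))
    y = _encode_labels(np.asarray(labels), classes)

    rng = np.random.default_rng(config.seed)
    net = Network(config, architecture, rng)
    opt = Adam(list(net._all_layers()), lr=config.learning_rate)
    history = {"train_loss": [], "train_acc": []}
    if validation is not None:
        xv = _as_batch(validation[0], config)
        yv = _encode_labels(np.asarray(validation[1]), classes)
        history["val_loss"] = []
        history["val_acc"] = []

    n = len(x)
    for epoch in range(config.epochs):
        # cosine decay to 10% of the base rate over the run
        frac = epoch / max(config.epochs - 1, 1)
        opt.lr = config.learning_rate * (0.55 + 0.45 * np.cos(np.pi * frac))
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            logits = net.forward(x[idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            net.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int(np.sum(np.argmax(logits, axis=1) == y[idx]))
        history["train_loss"].append(float(np.sum(losses) / n))
        history["train_acc"].append(correct / n)
        if validation is not None:
            vlogits = net.forward(xv, training=False)
            vloss, _ = softmax_cross_entropy(vlogits, yv)
            history["val_loss"].append(vloss)
            history["val_acc"].append(
                float(np.mean(np.argmax(vlogits, axis=1) == yv))
            )
    return TrainedModel(network=net, classes=classes, config=config,
                        architecture=architecture, history=history)


def classify(window: np.ndarray, model: TrainedModel) -> np.ndarray:
    """Class-probability vector(s) for one window or a batch."""
    probs = model.predict_proba(window)
    return probs[0] if np.asarray(window).ndim == 2 else probs


def save_model(model: TrainedModel, path) -> None:
    """Write a self-describing single-file checkpoint (.npz): architecture,
    config, label vocabulary and every parameter array."""
    import json

    arrays = {}
    for i, layer in enumerate(model.network._all_layers()):
        for key, value in layer.params.items():
            arrays[f"p{i}_{key}"] = value
    meta = {
        "architecture": model.architecture,
        "config": model.config.to_dict(),
        "classes": [str(c) for c in model.classes],
        "history": model.history,
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta, sort_keys=True).encode(),
                                   dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> TrainedModel:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = dict(meta["config"])
        cfg["shallow_branch"] = tuple(cfg["shallow_branch"])
        cfg["deep_branch"] = tuple(cfg["deep_branch"])
        cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
        config = ModelConfig(**cfg)
        net = Network(config, meta["architecture"],
                      np.random.default_rng(config.seed))
        for i, layer in enumerate(net._all_layers()):
            for key in layer.params:
                layer.params[key][...] = data[f"p{i}_{key}"]
    return TrainedModel(network=net, classes=np.asarray(meta["classes"]),
                        config=config, architecture=meta["architecture"],
                        history=meta["history"])


class PpgStageClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style estimator over the architecture variants.

    ``X`` is a 3-D array (n_windows, n_channels, window_len); ``y`` holds
    the stage labels.  ``window_len`` and ``n_classes`` are inferred from
    the data at fit time.
    """

    def __init__(
        self,
        architecture: str = "mcnn_lstm_attention",
        shallow_branch: tuple[int, int, int] = (21, 2, 16),
        deep_branch: tuple[int, int, int] = (5, 4, 32),
        pool_width: int = 2,
        lstm_hidden: int = 64,
        lstm_layers: int = 2,
        attention_dim: int = 64,
        fc_sizes: tuple[int, ...] = (64,),
        dropout_p: float = 0.5,
        epochs: int = 30,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ) -> None:
        self.architecture = architecture
        self.shallow_branch = shallow_branch
        self.deep_branch = deep_branch
        self.pool_width = pool_width
        self.lstm_hidden = lstm_hidden
        self.lstm_layers = lstm_layers
        self.attention_dim = attention_dim
        self.fc_sizes = fc_sizes
        self.dropout_p = dropout_p
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def _config(self, window_len: int, n_classes: int) -> ModelConfig:
        return ModelConfig(
            window_len=window_len,
            shallow_branch=tuple(self.shallow_branch),
            deep_branch=tuple(self.deep_branch),
            pool_width=self.pool_width,
            lstm_hidden=self.lstm_hidden,
            lstm_layers=self.lstm_layers,
            attention_dim=self.attention_dim,
            fc_sizes=tuple(self.fc_sizes),
            dropout_p=self.dropout_p,
            n_classes=n_classes,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.seed,
        )

    def fit(self, X, y, validation=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, n_channels, window_len)")
        y = np.asarray(y)
        classes = np.unique(y)
        config = self._config(X.shape[2], len(classes))
        self.model_ = train(X, y, config, self.architecture, validation=validation)
        self.classes_ = self.model_.classes
        self.history_ = self.model_.history
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
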