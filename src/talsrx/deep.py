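"""The two neural branches: an ANN-LSTM hybrid and a Transformer encoder.

Both map the 192-value plate feature vector to probabilities over the 11
score classes, trained with Adam on cross-entropy for a fixed number of
epochs (no early stopping).

* ANN-LSTM: dense 192 -> 128 with ReLU, whose embedding is fed as a length-1
  sequence into a 128-unit LSTM; the final hidden state maps linearly to 11
  logits.  An alternative mode treats the plate as a 96-step sequence of
  (x, y) well pairs.
* Transformer: the plate is tokenized as 96 wells x 2 channels, linearly
  embedded to ``d_model`` (default 48), passed through 3 encoder layers
  (6-head self-attention + feed-forward + dropout 0.01 + residual layer
  norms), mean-pooled over tokens and mapped to 11 logits.  No positional
  encoding by default: the wells of a plate are an unordered set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import (
    Adam,
    DTYPE,
    Tensor,
    cross_entropy,
    dropout,
    layer_norm,
    softmax,
)
from .plate import N_CLASSES, N_FEATURES, N_WELLS

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class AnnLstmConfig:
    ann_hidden: int = 128
    lstm_hidden: int = 128
    lr: float = 0.01
    epochs: int = 500
    batch_size: int = 32
    #: "embedding" = length-1 sequence of the ANN output (default);
    #: "wells" = 96-step sequence of (x, y) pairs after the ANN layer acts per token.
    sequence_mode: str = "embedding"

    def __post_init__(self) -> None:
        if min(self.ann_hidden, self.lstm_hidden, self.epochs, self.batch_size) < 1:
            raise ValueError("hidden sizes, epochs and batch size must be positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.sequence_mode not in ("embedding", "wells"):
            raise ValueError(f"unknown sequence_mode {self.sequence_mode!r}")


@dataclass
class TransformerConfig:
    n_layers: int = 3
    nhead: int = 6
    d_model: int = 48
    dim_feedforward: int = 96
    dropout: float = 0.01
    lr: float = 0.001
    epochs: int = 500
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.d_model % self.nhead != 0:
            raise ValueError(
                f"d_model ({self.d_model}) must be divisible by nhead ({self.nhead})"
            )
        if min(self.n_layers, self.nhead, self.d_model, self.epochs,
               self.batch_size) < 1:
            raise ValueError("layer counts and sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def _init(rng: np.random.Generator, *shape, fan_in: int | None = None) -> Tensor:
    fan_in = fan_in if fan_in is not None else shape[0]
    bound = float(np.sqrt(1.0 / fan_in))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class _NeuralModel:
    """Shared training loop: Adam + cross-entropy for a fixed epoch count.

    Inputs are standardized per feature with statistics frozen at fit time:
    the raw relative-fluorescence features are all-positive with a strong
    common mean, which saturates the gated/attention nonlinearities at the
    default learning rates.
    """

    config = None
    params: list[Tensor]

    def _forward(self, X: np.ndarray, training: bool,
                 rng: np.random.Generator | None) -> Tensor:
        raise NotImplementedError

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self._mu) / self._sd

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "_NeuralModel":
        X = np.asarray(X, dtype=DTYPE)
        y = np.asarray(y, dtype=int)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd == 0, 1.0, sd).astype(DTYPE)
        X = self._standardize(X)
        rng = np.random.default_rng(seed)
        opt = Adam(self.params, lr=self.config.lr)
        n = X.shape[0]
        bs = min(self.config.batch_size, n)
        self.loss_history: list[float] = []
        for epoch in range(self.config.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                logits = self._forward(X[idx], training=True, rng=rng)
                loss = cross_entropy(logits, y[idx])
                val = float(loss.data)
                if not np.isfinite(val):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch} (lr={self.config.lr})"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += val * len(idx)
            self.loss_history.append(epoch_loss / n)
        self.final_loss = self.loss_history[-1]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._standardize(np.asarray(X, dtype=DTYPE))
        logits = self._forward(X, training=False, rng=None)
        return softmax(logits).data.astype(float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


class AnnLstmModel(_NeuralModel):
    def __init__(self, config: AnnLstmConfig | None = None, seed: int = 0,
                 n_features: int = N_FEATURES, n_classes: int = N_CLASSES):
        self.config = config or AnnLstmConfig()
        self.n_features = n_features
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        c = self.config
        in_dim = n_features if c.sequence_mode == "embedding" else 2
        h, lh = c.ann_hidden, c.lstm_hidden
        self.W_ann = _init(rng, in_dim, h)
        self.b_ann = _zeros(h)
        # one weight matrix per LSTM gate (input, forget, cell, output)
        self.gates = {}
        for gname in ("i", "f", "g", "o"):
            self.gates[gname] = (
                _init(rng, h, lh), _init(rng, lh, lh, fan_in=lh), _zeros(lh)
            )
        self.W_out = _init(rng, lh, n_classes)
        self.b_out = _zeros(n_classes)
        self.params = [self.W_ann, self.b_ann, self.W_out, self.b_out]
        for w_x, w_h, b in self.gates.values():
            self.params += [w_x, w_h, b]

    def _lstm_step(self, x_t: Tensor, h: Tensor | None, c: Tensor | None):
        def gate(name):
            w_x, w_h, b = self.gates[name]
            pre = x_t @ w_x + b
            if h is not None:
                pre = pre + h @ w_h
            return pre

        i = gate("i").sigmoid()
        f = gate("f").sigmoid()
        g = gate("g").tanh()
        o = gate("o").sigmoid()
        c_new = i * g if c is None else f * c + i * g
        return o * c_new.tanh(), c_new

    def _forward(self, X, training, rng):
        xt = Tensor(X)
        if self.config.sequence_mode == "embedding":
            emb = (xt @ self.W_ann + self.b_ann).relu()
            h, _ = self._lstm_step(emb, None, None)
        else:
            n = X.shape[0]
            seq = X.reshape(n, N_WELLS, 2)
            h = c = None
            for t in range(N_WELLS):
                step = (Tensor(seq[:, t, :]) @ self.W_ann + self.b_ann).relu()
                h, c = self._lstm_step(step, h, c)
        return h @ self.W_out + self.b_out


class TransformerModel(_NeuralModel):
    def __init__(self, config: TransformerConfig | None = None, seed: int = 0,
                 n_features: int = N_FEATURES, n_classes: int = N_CLASSES):
        self.config = config or TransformerConfig()
        if n_features % 2 != 0:
            raise ValueError("feature count must be even (x, y per well)")
        self.n_tokens = n_features // 2
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        c = self.config
        d, ff = c.d_model, c.dim_feedforward
        self.embed_W = _init(rng, 2, d)
        self.embed_b = _zeros(d)
        self.layers = []
        for _ in range(c.n_layers):
            layer = {
                "Wq": _init(rng, d, d), "Wk": _init(rng, d, d),
                "Wv": _init(rng, d, d), "Wo": _init(rng, d, d),
                "ln1_g": Tensor(np.ones(d), requires_grad=True),
                "ln1_b": _zeros(d),
                "W1": _init(rng, d, ff), "b1": _zeros(ff),
                "W2": _init(rng, ff, d), "b2": _zeros(d),
                "ln2_g": Tensor(np.ones(d), requires_grad=True),
                "ln2_b": _zeros(d),
            }
            self.layers.append(layer)
        self.out_W = _init(rng, d, n_classes)
        self.out_b = _zeros(n_classes)
        self.params = [self.embed_W, self.embed_b, self.out_W, self.out_b]
        for layer in self.layers:
            self.params += list(layer.values())

    def _attention(self, x: Tensor, layer: dict, training: bool, rng) -> Tensor:
        c = self.config
        B, T, d = x.shape
        H, dh = c.nhead, d // c.nhead

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, dh).transpose((0, 2, 1, 3))

        # fold the 1/sqrt(d_head) scale into q: cheaper than scaling the
        # (B, H, T, T) score matrix
        q = heads(x @ layer["Wq"]) * float(1.0 / np.sqrt(dh))
        k, v = heads(x @ layer["Wk"]), heads(x @ layer["Wv"])
        scores = q @ k.transpose((0, 1, 3, 2))
        attn = softmax(scores, axis=-1) @ v                     # (B, H, T, dh)
        merged = attn.transpose((0, 2, 1, 3)).reshape(B, T, d)
        return dropout(merged @ layer["Wo"], c.dropout, rng, training)

    def _forward(self, X, training, rng):
        n = X.shape[0]
        tokens = Tensor(X.reshape(n, self.n_tokens, 2))
        x = tokens @ self.embed_W + self.embed_b
        c = self.config
        for layer in self.layers:
            x = layer_norm(x + self._attention(x, layer, training, rng),
                           layer["ln1_g"], layer["ln1_b"])
            ffn = ((x @ layer["W1"] + layer["b1"]).relu() @ layer["W2"] + layer["b2"])
            x = layer_norm(x + dropout(ffn, c.dropout, rng, training),
                           layer["ln2_g"], layer["ln2_b"])
        pooled = x.mean(axis=1)
        return pooled @ self.out_W + self.out_b


def fit_ann_lstm(X, y, config: AnnLstmConfig | None = None, seed: int = 0) -> AnnLstmModel:
    """Train the ANN-LSTM branch; returns a model with ``predict_proba``."""
    X = np.asarray(X, dtype=float)
    model = AnnLstmModel(config, seed=seed, n_features=X.shape[1])
    return model.fit(X, y, seed=seed + 1)


def fit_transformer(X, y, config: TransformerConfig | None = None,
                    seed: int = 0) -> TransformerModel:
    """Train the Transformer branch; returns a model with ``predict_proba``."""
    X = np.asarray(X, dtype=float)
    model = TransformerModel(config, seed=seed, n_features=X.shape[1])
    return model.fit(X, y, seed=seed + 1)
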