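"""Attention-based bidirectional LSTM feature extractor.

Each 0.4-s segment is consumed time-major: 64 time steps of 64-channel
vectors.  A forward and a time-reversed LSTM pass produce per-step outputs
that are concatenated, pooled by a learned softmax attention over time, and
fed through dropout → fully connected layer → batch norm → softplus → a
4-unit softmax head.  Training minimizes the mean squared Euclidean
distance between the normalized output and the one-hot label (cross-entropy
available as a config switch) with an L2 penalty on the weight matrices,
optimized by Adam.  After training, the post-softplus FC activations are
the per-segment features handed to the graph classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor, sigmoid, softmax, softplus, stack, tanh, tensor
from .data import SegmentDataset
from .layers import BatchNorm, Dense, dropout, glorot, param

logger = logging.getLogger(__name__)


@dataclass
class LSTMParams:
    """All trainable tensors of one LSTM cell (input/forget/output/candidate)."""

    W_xi: Tensor
    W_xf: Tensor
    W_xo: Tensor
    W_xg: Tensor
    W_hi: Tensor
    W_hf: Tensor
    W_ho: Tensor
    W_hg: Tensor
    b_i: Tensor
    b_f: Tensor
    b_o: Tensor
    b_g: Tensor

    @staticmethod
    def init(rng: np.random.Generator, input_size: int, cell_size: int) -> "LSTMParams":
        gx = lambda: param(glorot(rng, input_size, cell_size))
        gh = lambda: param(glorot(rng, cell_size, cell_size))
        zeros = lambda: param(np.zeros(cell_size))
        return LSTMParams(
            gx(), gx(), gx(), gx(),
            gh(), gh(), gh(), gh(),
            zeros(),
            param(np.ones(cell_size)),  # forget-gate bias 1: remember by default
            zeros(), zeros(),
        )

    def parameters(self):
        return [
            self.W_xi, self.W_xf, self.W_xo, self.W_xg,
            self.W_hi, self.W_hf, self.W_ho, self.W_hg,
            self.b_i, self.b_f, self.b_o, self.b_g,
        ]

    def weights(self):
        return self.parameters()[:8]


@dataclass
class CellState:
    c: Tensor  # long-term state
    h: Tensor  # short-term state

    @staticmethod
    def zeros(batch: int, cell_size: int) -> "CellState":
        return CellState(Tensor(np.zeros((batch, cell_size))), Tensor(np.zeros((batch, cell_size))))


@dataclass
class AttentionParams:
    W_w: Tensor  # (2*cell_size, attention_size)
    b_w: Tensor  # (attention_size,)
    u_w: Tensor  # (attention_size, 1) learned context vector

    @staticmethod
    def init(rng, in_size: int, attention_size: int) -> "AttentionParams":
        return AttentionParams(
            param(glorot(rng, in_size, attention_size)),
            param(np.zeros(attention_size)),
            param(glorot(rng, attention_size, 1)),
        )

    def parameters(self):
        return [self.W_w, self.b_w, self.u_w]

    def weights(self):
        return [self.W_w, self.u_w]


@dataclass
class ExtractorConfig:
    input_size: int = 64
    max_time: int = 64
    cell_size: int = 256
    attention_size: int = 8
    fc_size: int = 64
    n_classes: int = 4
    dropout_rate: float = 0.25
    l2_coeff: float = 1e-7
    learning_rate: float = 1e-4
    batch_size: int = 1024
    epochs: int = 300
    loss: str = "mse"  # squared Euclidean distance to one-hot; or "cross_entropy"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        for name in ("input_size", "max_time", "cell_size", "attention_size", "fc_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FeatureTable:
    """Per-segment FC-layer activations (strictly positive under softplus)."""

    features: np.ndarray  # n_samples x fc_size
    labels: np.ndarray  # n_samples
    test_masks: np.ndarray | None = None  # carried over from the dataset

    def __len__(self):
        return len(self.labels)


def lstm_step(x_t, prev: CellState, p: LSTMParams):
    """One LSTM cell update; returns (new state, output y_t = h_t)."""
    x_t = tensor(x_t)
    if not np.all(np.isfinite(x_t.data)):
        raise ValueError("non-finite input to LSTM step")
    if x_t.ndim == 1:
        x_t = x_t.reshape(1, -1)
    h, c = prev.h, prev.c
    i = sigmoid(x_t @ p.W_xi + h @ p.W_hi + p.b_i)
    f = sigmoid(x_t @ p.W_xf + h @ p.W_hf + p.b_f)
    o = sigmoid(x_t @ p.W_xo + h @ p.W_ho + p.b_o)
    g = tanh(x_t @ p.W_xg + h @ p.W_hg + p.b_g)
    c_new = f * c + i * g
    h_new = o * tanh(c_new)
    return CellState(c_new, h_new), h_new


def bilstm_forward(x_seq, p_fwd: LSTMParams, p_bwd: LSTMParams):
    """Bidirectional unrolling over a (batch, time, channels) sequence.

    The backward pass consumes the time-reversed sequence and its outputs
    are re-reversed, so step t of the result is [forward_t; backward_t].
    Returns a list of (batch, 2*cell_size) outputs, one per time step.
    """
    x_seq = np.asarray(x_seq.data if isinstance(x_seq, Tensor) else x_seq, float)
    if x_seq.ndim == 2:
        x_seq = x_seq[None]
    B, T, _ = x_seq.shape
    cell = p_fwd.b_i.shape[0]
    if p_bwd.b_i.shape[0] != cell:
        raise ValueError("forward and backward cells must share cell_size")

    def unroll(p, xs):
        state = CellState.zeros(B, cell)
        ys = []
        for t in range(xs.shape[1]):
            state, y = lstm_step(Tensor(xs[:, t, :]), state, p)
            ys.append(y)
        return ys

    fwd = unroll(p_fwd, x_seq)
    bwd = unroll(p_bwd, x_seq[:, ::-1, :])[::-1]
    return [ad.concat([f, b], axis=-1) for f, b in zip(fwd, bwd)]


def attention_pool(ys, a: AttentionParams):
    """Softmax attention over time: u_t = tanh(W_w y_t + b_w), scores u_tᵀu_w.

    Returns (context vector s, attention weights α); α sums to one.
    """
    if len(ys) == 0:
        raise ValueError("empty sequence")
    ys = [tensor(y) for y in ys]
    scores = [tanh(y @ a.W_w + a.b_w) @ a.u_w for y in ys]  # each (B, 1)
    e = ad.concat(scores, axis=-1)  # (B, T)
    alpha = softmax(e, axis=-1)
    weighted = [alpha[:, t : t + 1] * y for t, y in enumerate(ys)]
    s = weighted[0]
    for w in weighted[1:]:
        s = s + w
    return s, alpha


class FeatureExtractor:
    """BiLSTM + attention + FC head; the trainable feature extractor."""

    def __init__(self, config: ExtractorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        self.p_fwd = LSTMParams.init(rng, config.input_size, config.cell_size)
        self.p_bwd = LSTMParams.init(rng, config.input_size, config.cell_size)
        self.attn = AttentionParams.init(rng, 2 * config.cell_size, config.attention_size)
        self.fc = Dense(rng, 2 * config.cell_size, config.fc_size)
        self.bn = BatchNorm(config.fc_size)
        self.out = Dense(rng, config.fc_size, config.n_classes)
        self._trained = False

    def parameters(self):
        return (
            self.p_fwd.parameters()
            + self.p_bwd.parameters()
            + self.attn.parameters()
            + self.fc.parameters()
            + self.bn.parameters()
            + self.out.parameters()
        )

    def weights(self):
        return (
            self.p_fwd.weights()
            + self.p_bwd.weights()
            + self.attn.weights()
            + self.fc.weights()
            + self.out.weights()
        )

    def forward(self, segments: np.ndarray, train: bool = False):
        """Segments (batch, channels, timesteps) → (class scores, FC features).

        The segment matrix is transposed to time-major form so each of the
        `max_time` steps presents one `input_size`-channel sample vector.
        """
        x = np.asarray(segments, float)
        if x.ndim == 2:
            x = x[None]
        x = np.swapaxes(x, 1, 2)  # -> (batch, time, channels)
        if not self._trained and not train:
            logger.info("extractor used in eval mode before training (random features)")
        ys = bilstm_forward(x, self.p_fwd, self.p_bwd)
        s, _alpha = attention_pool(ys, self.attn)
        s = dropout(s, self.config.dropout_rate, self.rng, train)
        fc_act = softplus(self.bn(self.fc(s), train))
        scores = softmax(self.out(fc_act), axis=-1)
        return scores, fc_act


def extractor_forward(segments, model: FeatureExtractor, train: bool = False):
    """Functional wrapper: returns (normalized class scores, fc activations)."""
    return model.forward(segments, train=train)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    eye = np.eye(n_classes)
    return eye[np.asarray(labels, int)]


def _loss(model: FeatureExtractor, scores: Tensor, labels: np.ndarray) -> Tensor:
    cfg = model.config
    if cfg.loss == "mse":
        target = Tensor(_one_hot(labels, cfg.n_classes))
        diff = scores - target
        data_loss = (diff * diff).sum(axis=1).mean()
    elif cfg.loss == "cross_entropy":
        picked = ad.log(scores[np.arange(len(labels)), np.asarray(labels, int)] + 1e-12)
        data_loss = -picked.mean()
    else:
        raise ValueError(f"unknown loss {cfg.loss!r}")
    reg = Tensor(0.0)
    for w in model.weights():
        reg = reg + (w * w).sum()
    return data_loss + cfg.l2_coeff * reg


def train_extractor(
    train_data: SegmentDataset | tuple, config: ExtractorConfig
) -> tuple[FeatureExtractor, dict]:
    """Train the extractor; returns (model, log with per-epoch loss/accuracy)."""
    if isinstance(train_data, SegmentDataset):
        X, y = train_data.data, train_data.labels
    else:
        X, y = train_data
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(X) < 1:
        raise ValueError("need at least one training batch")
    model = FeatureExtractor(config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    log = {"loss": [], "accuracy": []}
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(X))
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            scores, _ = model.forward(X[idx], train=True)
            loss = _loss(model, scores, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; training diverged"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
            ep_correct += int((scores.data.argmax(axis=1) == y[idx]).sum())
        log["loss"].append(ep_loss / len(X))
        log["accuracy"].append(ep_correct / len(X))
        logger.debug(
            "extractor epoch %d: loss %.4f acc %.3f",
            epoch, log["loss"][-1], log["accuracy"][-1],
        )
    model._trained = True
    return model, log


def extract_features(
    ds: SegmentDataset, model: FeatureExtractor, batch_size: int = 256
) -> FeatureTable:
    """FC-layer activations for every segment, in eval mode, order preserved."""
    feats = np.empty((len(ds), model.config.fc_size))
    for start in range(0, len(ds), batch_size):
        _, fc = model.forward(ds.data[start : start + batch_size], train=False)
        feats[start : start + len(fc.data)] = fc.data
    return FeatureTable(feats, ds.labels.copy(), ds.test_masks)
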