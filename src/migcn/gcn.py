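"""Chebyshev spectral graph-convolutional classifier.

Filters are K-term Chebyshev polynomials in the rescaled Laplacian,
y = Σ_k T_k(L̃) x θ_k with T_k(x) = 2x T_{k-1}(x) − T_{k-2}(x), evaluated
by matrix products only — no eigendecomposition.  The network stacks graph
convolution → batch norm → softplus → 1-D graph max pooling (size 2, over
the Graclus binary-tree ordering), then a dense softmax head.  "Second
order" polynomials correspond to K = 3 terms (k = 0, 1, 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor, softmax, softplus, tensor
from .coarsening import CoarseningHierarchy, graclus_coarsen, graph_maxpool, permute_signal
from .extractor import FeatureTable
from .graph import FeatureGraph, normalized_laplacian
from .layers import BatchNorm, Dense, glorot, param

logger = logging.getLogger(__name__)


@dataclass
class ChebFilterParams:
    """theta: (K, f_in, f_out) Chebyshev coefficients of one layer."""

    theta: Tensor

    @property
    def K(self) -> int:
        return self.theta.shape[0]

    @staticmethod
    def init(rng, K: int, f_in: int, f_out: int) -> "ChebFilterParams":
        scale = np.sqrt(6.0 / (K * f_in + f_out))
        return ChebFilterParams(param(rng.uniform(-scale, scale, (K, f_in, f_out))))


def chebyshev_filter(x, L_scaled: np.ndarray, params: ChebFilterParams) -> Tensor:
    """Filter a (batch, nodes, f_in) signal; returns (batch, nodes, f_out).

    Accepts (nodes, f_in) for a single sample.
    """
    x = tensor(x)
    single = x.ndim == 2
    if single:
        x = x.reshape(1, *x.shape)
    L = np.asarray(L_scaled, float)
    theta = params.theta
    Tk_prev, Tk = None, x
    y = Tk @ theta[0]
    if params.K > 1:
        Tk_prev, Tk = Tk, Tensor(L) @ x
        y = y + Tk @ theta[1]
    for k in range(2, params.K):
        Tk_prev, Tk = Tk, 2.0 * (Tensor(L) @ Tk) - Tk_prev
        y = y + Tk @ theta[k]
    return y.reshape(*y.shape[1:]) if single else y


def spectral_filter_oracle(x: np.ndarray, L: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Brute-force spectral-domain reference: y = U gθ(Λ) Uᵀ x per channel pair.

    Eigendecomposes the (unscaled) normalized Laplacian, evaluates the
    Chebyshev filter on the rescaled eigenvalues and reconstructs.  Test
    utility for small graphs only.
    """
    x = np.asarray(x, float)
    if x.ndim == 2:
        x = x[None]
    theta = np.asarray(theta, float)
    K, f_in, f_out = theta.shape
    lam, U = np.linalg.eigh(L)
    lam_max = lam[-1] if lam[-1] > 0 else 2.0
    lam_scaled = 2.0 * lam / lam_max - 1.0
    # Chebyshev polynomials on scaled eigenvalues
    Tk = np.ones((K, len(lam)))
    if K > 1:
        Tk[1] = lam_scaled
    for k in range(2, K):
        Tk[k] = 2.0 * lam_scaled * Tk[k - 1] - Tk[k - 2]
    xhat = np.einsum("nm,bmi->bni", U.T, x)
    y = np.zeros((x.shape[0], x.shape[1], f_out))
    for j in range(f_out):
        for i in range(f_in):
            g = (theta[:, i, j][:, None] * Tk).sum(axis=0)  # filter response g(λ)
            y[:, :, j] += np.einsum("nm,bm->bn", U, g * xhat[:, :, i])
    return y


@dataclass
class GCNConfig:
    filters_per_layer: list = field(default_factory=lambda: [16, 32, 64, 128, 256, 512])
    pool_per_layer: list = field(default_factory=lambda: [2, 2, 2, 2, 2, 2])
    K: int = 3  # "second-order" polynomial: terms k = 0, 1, 2
    n_classes: int = 4
    l2_coeff: float = 1e-7
    batch_size: int = 16
    learning_rate: float = 1e-7  # faithful default; impractically slow at desk scale
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if len(self.filters_per_layer) != len(self.pool_per_layer):
            raise ValueError("filters_per_layer and pool_per_layer must align")
        if self.K < 1:
            raise ValueError("need at least one Chebyshev term")


class GCNModel:
    """Stack of Chebyshev-filter layers over a coarsening hierarchy."""

    def __init__(self, config: GCNConfig, graph: FeatureGraph | np.ndarray):
        self.config = config
        A = graph.A if isinstance(graph, FeatureGraph) else np.asarray(graph)
        n_levels = len(config.filters_per_layer)
        if any(p != 2 for p in config.pool_per_layer):
            raise ValueError("binary-tree coarsening supports pool size 2 only")
        total_pool = int(np.prod(config.pool_per_layer))
        self.hierarchy = graclus_coarsen(A, n_levels, seed=config.seed)
        if self.hierarchy.padded_size(0) < total_pool:
            raise ValueError(
                f"padded graph ({self.hierarchy.padded_size(0)} nodes) too small "
                f"for total pooling {total_pool}"
            )
        # scaled Laplacian of every level's padded graph
        self.laplacians = [
            normalized_laplacian(g)[3] for g in self.hierarchy.graphs
        ]
        rng = np.random.default_rng(config.seed)
        self.filters: list[ChebFilterParams] = []
        self.bns: list[BatchNorm] = []
        f_in = 1
        for f_out in config.filters_per_layer:
            self.filters.append(ChebFilterParams.init(rng, config.K, f_in, f_out))
            self.bns.append(BatchNorm(f_out))
            f_in = f_out
        n_last = self.hierarchy.padded_size(0) // total_pool
        self.out = Dense(rng, n_last * f_in, config.n_classes)
        # positions that descend from at least one real node, per level
        self._masks = self.hierarchy.masks

    def parameters(self):
        ps = [f.theta for f in self.filters] + self.out.parameters()
        for bn in self.bns:
            ps.extend(bn.parameters())
        return ps

    def weights(self):
        return [f.theta for f in self.filters] + self.out.weights()

    def forward(self, features: np.ndarray, train: bool = False) -> Tensor:
        """(batch, n_features) feature rows → (batch, n_classes) probabilities.

        Each row enters as a one-channel signal on the feature graph.
        """
        x = np.asarray(features, float)
        if x.ndim == 1:
            x = x[None]
        sig = permute_signal(x[:, :, None], self.hierarchy)
        for level, (flt, bn, pool) in enumerate(
            zip(self.filters, self.bns, self.config.pool_per_layer)
        ):
            sig = chebyshev_filter(sig, self.laplacians[level], flt)
            sig = softplus(bn(sig, train))
            # keep fake positions at zero so they never win a max
            mask = self._level_mask(level, sig.shape[1])
            sig = sig * Tensor(mask[None, :, None])
            sig = graph_maxpool(sig, pool)
        flat = sig.reshape(sig.shape[0], -1)
        return softmax(self.out(flat), axis=-1)

    def _level_mask(self, level: int, size: int) -> np.ndarray:
        mask = self._masks[level].astype(float)
        # successive pools within the hierarchy keep sizes aligned by design
        if len(mask) != size:
            raise ValueError("hierarchy/config depth mismatch")
        return mask


def gcn_forward(features, model: GCNModel, train: bool = False) -> Tensor:
    """Functional wrapper; probabilities sum to one per row."""
    return model.forward(features, train=train)


def train_gcn(
    features: FeatureTable | tuple,
    graph: FeatureGraph | np.ndarray,
    config: GCNConfig,
) -> tuple[GCNModel, dict]:
    """Train with cross-entropy + L2 on filter/dense weights, Adam updates."""
    if isinstance(features, FeatureTable):
        X, y = features.features, features.labels
    else:
        X, y = features
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    model = GCNModel(config, graph)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    log = {"loss": [], "accuracy": []}
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(X))
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            probs = model.forward(X[idx], train=True)
            picked = ad.log(probs[np.arange(len(idx)), y[idx]] + 1e-12)
            loss = -picked.mean()
            for w in model.weights():
                loss = loss + config.l2_coeff * (w * w).sum()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; training diverged"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
            ep_correct += int((probs.data.argmax(axis=1) == y[idx]).sum())
        log["loss"].append(ep_loss / len(X))
        log["accuracy"].append(ep_correct / len(X))
        logger.debug(
            "gcn epoch %d: loss %.4f acc %.3f", epoch, log["loss"][-1], log["accuracy"][-1]
        )
    return model, log


def predict_proba(model: GCNModel, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Eval-mode class probabilities for a feature table."""
    out = np.empty((len(X), model.config.n_classes))
    for start in range(0, len(X), batch_size):
        out[start : start + batch_size] = model.forward(
            X[start : start + batch_size], train=False
        ).data
    return out
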