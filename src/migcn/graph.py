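"""Feature-correlation graph: Pearson matrix, adjacency, normalized Laplacian.

The learned features form the nodes of a complete weighted graph whose edge
weights are absolute Pearson correlations, A = |P| − I.  The classifier
filters signals on this graph through the symmetric normalized Laplacian
L = I − D^{−1/2} A D^{−1/2} (spectrum in [0, 2]), rescaled to
L̃ = 2L/λ_max − I so Chebyshev polynomials are evaluated on [−1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class FeatureGraph:
    P: np.ndarray
    A: np.ndarray
    D: np.ndarray
    L: np.ndarray
    lambda_max: float
    L_scaled: np.ndarray

    @property
    def n(self) -> int:
        return self.A.shape[0]


def pearson_matrix(features: np.ndarray) -> np.ndarray:
    """Pearson correlation over columns of an (n_samples x n_features) table.

    Zero-variance features get zero off-diagonal correlation (the node
    becomes isolated) instead of propagating NaNs; the diagonal is exactly 1.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D table with at least two samples")
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance feature(s); their correlations set to 0",
            int(degenerate.sum()),
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    Z = Xc / safe_sd
    P = Z.T @ Z / X.shape[0]
    P[degenerate, :] = 0.0
    P[:, degenerate] = 0.0
    P = (P + P.T) / 2.0
    np.clip(P, -1.0, 1.0, out=P)
    np.fill_diagonal(P, 1.0)
    return P


def adjacency_from_pearson(P: np.ndarray) -> np.ndarray:
    """A = |P| − I: zero diagonal, entries in [0, 1], symmetric."""
    P = np.asarray(P, dtype=float)
    if np.abs(np.diag(P) - 1.0).max() > 1e-9:
        raise ValueError("Pearson matrix must have unit diagonal")
    A = np.abs(P)
    np.fill_diagonal(A, 0.0)
    return A


def normalized_laplacian(A: np.ndarray, lambda_max_mode: str = "exact"):
    """Degree matrix, normalized Laplacian, λ_max and the scaled Laplacian.

    Isolated nodes (zero degree) get L_ii = 1 with zero off-diagonals — the
    convention that keeps the spectrum inside [0, 2].  `lambda_max_mode`
    'exact' uses a dense symmetric eigensolve; 'upper-bound' uses the common
    λ_max = 2 shortcut.

    Returns ``(D, L, lambda_max, L_scaled)``.
    """
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("adjacency entries must be nonnegative")
    if np.abs(A - A.T).max() > 1e-12:
        raise ValueError("adjacency must be symmetric")
    deg = A.sum(axis=1)
    D = np.diag(deg)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = deg[nz] ** -0.5
    L = np.eye(len(deg)) - (inv_sqrt[:, None] * A) * inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    if lambda_max_mode == "exact":
        lam = float(np.linalg.eigvalsh(L)[-1])
        if lam <= 0:  # empty graph: L = I, all eigenvalues 1
            lam = 2.0
    elif lambda_max_mode == "upper-bound":
        lam = 2.0
    else:
        raise ValueError("lambda_max_mode must be 'exact' or 'upper-bound'")
    L_scaled = 2.0 * L / lam - np.eye(len(deg))
    return D, L, lam, L_scaled


def build_feature_graph(
    features: np.ndarray, lambda_max_mode: str = "exact"
) -> FeatureGraph:
    """Pearson → adjacency → normalized/scaled Laplacian in one call.

    Build it from training-partition features to avoid test leakage (pass
    the full table for the faithful-but-leaky 'overall data' variant).
    """
    P = pearson_matrix(features)
    A = adjacency_from_pearson(P)
    D, L, lam, L_scaled = normalized_laplacian(A, lambda_max_mode)
    return FeatureGraph(P, A, D, L, lam, L_scaled)
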