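"""Herb-target interaction scoring head.

The N x M relation matrix is flattened and projected to a global feature
Z, then reverse-projected into an N x M x d tensor of per-pair relational
vectors. Each candidate pair (i, j) is scored from the fusion of its two
node embeddings and its pair relational vector — a dual-path design that
combines local semantics with global association structure — through a
two-hidden-layer MLP with a sigmoid output.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

logger = logging.getLogger("htinet")

MAX_PAIR_GRID = 20_000  # N*M cap: the reverse projection is d x (N*M*d)
EPS = 1e-7


class FusionParameters:
    """Projection, reverse projection, and MLP weights of the scoring head.

    Shapes are fixed by the pair-grid size (N herbs x M targets), the
    embedding dimension d and the hidden size d_h (which must be even;
    the second hidden layer has d_h / 2 units).
    """

    def __init__(self, n_herbs: int, n_targets: int, d: int, d_h: int, rng: np.random.Generator):
        if d_h % 2:
            raise ValueError("hidden size d_h must be even")
        if n_herbs * n_targets > MAX_PAIR_GRID:
            raise ValueError(
                f"pair grid {n_herbs}x{n_targets} exceeds the {MAX_PAIR_GRID} cap"
            )
        self.n_herbs, self.n_targets, self.d, self.d_h = n_herbs, n_targets, d, d_h
        nm = n_herbs * n_targets
        xav = lambda *shape: ad.xavier_uniform(rng, shape)
        self.W_p = Parameter(xav(nm, d), "W_p")  # applied as vec(M) @ W_p
        self.b_p = Parameter(np.zeros(d), "b_p")
        self.W_q = Parameter(xav(d, nm * d), "W_q")
        self.b_q = Parameter(np.zeros(nm * d), "b_q")  # independent bias of the reverse map
        self.W_1 = Parameter(xav(3 * d, d_h), "W_1")
        self.b_1 = Parameter(np.zeros(d_h), "b_1")
        self.W_2 = Parameter(xav(d_h, d_h // 2), "W_2")
        self.b_2 = Parameter(np.zeros(d_h // 2), "b_2")
        self.W_o = Parameter(xav(d_h // 2, 1), "W_o")
        self.b_o = Parameter(np.zeros(1), "b_o")

    def parameters(self) -> list[Parameter]:
        return [
            self.W_p, self.b_p, self.W_q, self.b_q,
            self.W_1, self.b_1, self.W_2, self.b_2, self.W_o, self.b_o,
        ]


def flatten_project(M: Tensor, params: FusionParameters) -> Tensor:
    """Global feature ``Z = ReLU(W_p vec(M) + b_p)``; vec is row-major
    (herb-major), so entry (i, j) sits at position i*M + j."""
    M = ad.as_tensor(M)
    if M.shape != (params.n_herbs, params.n_targets):
        raise ValueError(f"relation matrix shape {M.shape} does not match head")
    z_flat = M.reshape(-1)
    return ad.relu(z_flat @ params.W_p + params.b_p)


def global_reshape(Z: Tensor, params: FusionParameters) -> Tensor:
    """Reverse projection ``Z' = reshape(W_q Z + b, (N, M, d))`` — the
    per-pair relational vectors, row-major over the pair grid."""
    out = Z @ params.W_q + params.b_q
    return out.reshape(params.n_herbs, params.n_targets, params.d)


def pair_feature(h_herb: Tensor, h_target: Tensor, z_pair: Tensor) -> Tensor:
    """Hybrid feature ``f_ij = [h_i || h_j || Z'_ij]`` of dimension 3d."""
    for v in (h_herb, h_target, z_pair):
        if v.shape != h_herb.shape:
            raise ValueError("pair_feature inputs must share one dimension d")
    return ad.concat([ad.as_tensor(h_herb), ad.as_tensor(h_target), ad.as_tensor(z_pair)], axis=-1)


def mlp_score(f: Tensor, params: FusionParameters) -> Tensor:
    """Interaction probability via two ReLU hidden layers and a sigmoid.

    Accepts a single 3d vector or a (B, 3d) batch; returns matching shape.
    """
    f = ad.as_tensor(f)
    single = f.ndim == 1
    if single:
        f = f.reshape(1, -1)
    g1 = ad.relu(f @ params.W_1 + params.b_1.reshape(1, -1))
    g2 = ad.relu(g1 @ params.W_2 + params.b_2.reshape(1, -1))
    p = ad.sigmoid(g2 @ params.W_o + params.b_o.reshape(1, -1)).reshape(-1)
    return p[0] if single else p


def batch_pair_features(
    H_herb: Tensor, H_target: Tensor, Z_prime: Tensor, pairs: np.ndarray
) -> Tensor:
    """Fused features for an array of (herb_index, target_index) pairs."""
    pairs = np.asarray(pairs, dtype=np.intp)
    n_targets = Z_prime.shape[1]
    hi = ad.gather_rows(H_herb, pairs[:, 0])
    tj = ad.gather_rows(H_target, pairs[:, 1])
    flatZ = Z_prime.reshape(-1, Z_prime.shape[2])
    zij = ad.gather_rows(flatZ, pairs[:, 0] * n_targets + pairs[:, 1])
    return ad.concat([hi, tj, zij], axis=1)


def bce_loss(predictions: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy; probabilities are clamped to
    [EPS, 1-EPS] (with a warning if clamping was actually needed)."""
    predictions = ad.as_tensor(predictions)
    y = np.asarray(labels, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    if ((predictions.data <= 0) | (predictions.data >= 1)).any():
        warnings.warn("predictions at {0,1} clamped for BCE", RuntimeWarning, stacklevel=2)
    p = ad.clamp(predictions, EPS, 1.0 - EPS)
    yt = Tensor(y)
    loss = -(yt * ad.log(p) + (1.0 - yt) * ad.log(1.0 - p))
    return loss.mean()
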