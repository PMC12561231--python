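"""Similarity-network construction for herbs and targets.

Herbs are profiled by the efficacies and targets they connect to, targets
by their ingredients and herbs. Binary incidence vectors are compared with
cosine similarity; two views per entity are averaged; and a k-nearest-
neighbor pruning (top-alpha for herbs, top-beta for targets) keeps only
the strongest edges of the resulting herb-herb and target-target networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import HeteroGraph, SchemaError


@dataclass
class SimilarityConfig:
    """Top-k pruning levels for the two similarity networks."""

    alpha: int = 10  # neighbors kept per herb
    beta: int = 10  # neighbors kept per target

    def __post_init__(self) -> None:
        if self.alpha < 1 or self.beta < 1:
            raise ValueError("alpha and beta must be >= 1")


def incidence_matrix(
    g: HeteroGraph, entity: str, attribute: str, relation: str
) -> np.ndarray:
    """Binary entity-by-attribute membership matrix.

    ``X[i, j] = 1`` iff an edge of ``relation`` joins entity i to attribute
    j; rows follow the graph's node order for ``entity``. The relation may
    run in either direction between the two types.
    """
    rel = g.registry.get(relation)
    if rel is None:
        raise SchemaError(f"relation {relation!r} not in registry")
    if (rel.src, rel.dst) == (entity, attribute):
        B = g.biadjacency(relation)
    elif (rel.src, rel.dst) == (attribute, entity):
        B = g.biadjacency(relation).T
    else:
        raise SchemaError(
            f"relation {relation} joins {rel.src}-{rel.dst}, not {entity}-{attribute}"
        )
    return (B.toarray() > 0).astype(float)


def cosine_similarity_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of rows; all-zero rows yield 0 everywhere."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = X / safe[:, None]
    S = U @ U.T
    S[norms == 0, :] = 0.0
    S[:, norms == 0] = 0.0
    np.clip(S, 0.0, 1.0, out=S)
    return S


def average_similarity(S1: np.ndarray, S2: np.ndarray) -> np.ndarray:
    if S1.shape != S2.shape:
        raise ValueError(f"shape mismatch {S1.shape} vs {S2.shape}")
    return (np.asarray(S1, float) + np.asarray(S2, float)) / 2.0


def top_k_network(
    S: np.ndarray, k: int, ids: list[str] | None = None
) -> list[tuple[str, str, float]]:
    """Keep each entity's k most-similar positive neighbors; union the picks.

    Self-similarity is excluded. Ties at the k-th rank are all included
    (closed top-k), so the result does not depend on index order. An edge is
    kept when either endpoint selects it, preserving symmetry of the
    undirected network. Returns one triple per unordered pair.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    keep: set[tuple[int, int]] = set()
    for i in range(n):
        row = S[i].copy()
        row[i] = -np.inf
        pos = np.flatnonzero(row > 0)
        if pos.size == 0:
            continue
        if pos.size <= k:
            chosen = pos
        else:
            kth = np.sort(row[pos])[::-1][k - 1]
            chosen = pos[row[pos] >= kth]  # closed top-k: ties included
        for j in chosen:
            keep.add((min(i, j), max(i, j)))
    return [(ids[i], ids[j], float(S[i, j])) for i, j in sorted(keep)]


def build_similarity_networks(
    g: HeteroGraph, config: SimilarityConfig | None = None
) -> HeteroGraph:
    """Attach pruned H-H and T-T similarity edges to a copy-in-place graph.

    Herb-herb similarity averages the efficacy-based and target-based herb
    views; target-target similarity averages the ingredient-based and
    herb-based target views. Edges carry the averaged similarity as weight.
    """
    config = config or SimilarityConfig()
    herb_ids = g.nodes["H"]
    target_ids = g.nodes["T"]

    S_h = average_similarity(
        cosine_similarity_matrix(incidence_matrix(g, "H", "E", "H-E")),
        cosine_similarity_matrix(incidence_matrix(g, "H", "T", "H-T")),
    )
    S_t = average_similarity(
        cosine_similarity_matrix(incidence_matrix(g, "T", "I", "I-T")),
        cosine_similarity_matrix(incidence_matrix(g, "T", "H", "H-T")),
    )
    for src, dst, w in top_k_network(S_h, config.alpha, herb_ids):
        g.add_edge("H-H", src, dst, w)
    for src, dst, w in top_k_network(S_t, config.beta, target_ids):
        g.add_edge("T-T", src, dst, w)
    g.validate()
    return g
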