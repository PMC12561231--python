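"""Metapath schemas, walk-semantics instance enumeration, and metapath
attention.

A metapath schema is an alternating node-type pattern such as H-I-H
("herbs sharing an ingredient"). An instance is a concrete walk whose
nodes realize the pattern; repeated nodes are allowed, so H1-I2-H1 is a
valid H-I-H instance. Metapath neighbors are the instance endpoints plus
the anchor itself.

The default schema lists (10 for herb anchors, 8 for target anchors, all
of length <= 5 nodes) are configuration shipped in ``schemas.yaml``, not
derived from the relation registry. The HIIH schema traverses an
ingredient-ingredient similarity relation that plain graphs may lack; it
is then skipped with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import scipy.sparse as sp
import yaml

from . import autodiff as ad
from .graph import HeteroGraph, GraphError, RelationType, SchemaError, default_registry

logger = logging.getLogger("htinet")

MAX_SCHEMA_NODES = 5


@dataclass(frozen=True)
class MetapathSchema:
    """A node-type sequence plus the relation joining each consecutive pair."""

    types: tuple[str, ...]
    relations: tuple[str, ...]
    name: str

    def __len__(self) -> int:
        return len(self.types)


def _pair_relation(a: str, b: str, registry: dict[str, RelationType]) -> str:
    for rel in registry.values():
        if {rel.src, rel.dst} == {a, b} or (rel.src == a and rel.dst == b):
            return rel.name
    raise SchemaError(f"no registered relation joins types {a} and {b}")


def parse_schema(
    pattern: str, registry: dict[str, RelationType] | None = None
) -> MetapathSchema:
    """Build a schema from a compact type string such as ``"HIH"``.

    The schema must start and end at the same type, contain 2..5 nodes,
    and every consecutive type pair must map to a registered relation.
    """
    registry = registry if registry is not None else default_registry()
    types = tuple(pattern.replace("-", ""))
    if not (2 <= len(types) <= MAX_SCHEMA_NODES):
        raise SchemaError(f"schema {pattern!r} must have 2..{MAX_SCHEMA_NODES} nodes")
    if types[0] != types[-1]:
        raise SchemaError(f"schema {pattern!r} must start and end at the same type")
    rels = tuple(_pair_relation(a, b, registry) for a, b in zip(types, types[1:]))
    return MetapathSchema(types=types, relations=rels, name="".join(types))


def default_schemas(
    node_type: str, registry: dict[str, RelationType] | None = None
) -> list[MetapathSchema]:
    """The curated schema lists for herb (10) and target (8) anchors."""
    if node_type not in ("H", "T"):
        raise SchemaError(f"no default schemas for anchor type {node_type!r}")
    with resources.files("htinet").joinpath("schemas.yaml").open() as fh:
        lists = yaml.safe_load(fh)
    return [parse_schema(p, registry) for p in lists[node_type]]


# -- enumeration ----------------------------------------------------------


def _typed_adjacency(g: HeteroGraph) -> dict[tuple[str, str], dict[str, list[str]]]:
    """Neighbor lists keyed by (relation, direction-target-type).

    ``adj[(r, t)][node]`` lists the type-``t`` neighbors of ``node`` under
    relation ``r``, sorted for deterministic traversal.
    """
    adj: dict[tuple[str, str], dict[str, list[str]]] = {}
    for rname, es in g.edges.items():
        rel = g.registry[rname]
        fwd = adj.setdefault((rname, rel.dst), {})
        bwd = adj.setdefault((rname, rel.src), {})
        for s, d, _ in es:
            fwd.setdefault(s, []).append(d)
            if rel.symmetric:
                fwd.setdefault(d, []).append(s)
            else:
                bwd.setdefault(d, []).append(s)
    for table in adj.values():
        for node in table:
            table[node].sort()
    return adj


def enumerate_instances(
    g: HeteroGraph, schema: MetapathSchema, anchor: str
) -> list[tuple[str, ...]]:
    """All walks from ``anchor`` realizing ``schema``, in lexicographic order.

    Walk semantics: a node may repeat within an instance (H1-I2-H1 is a
    valid H-I-H walk).
    """
    if g.type_of(anchor) != schema.types[0]:
        raise GraphError(
            f"anchor {anchor!r} is a {g.type_of(anchor)} node; schema {schema.name} starts at {schema.types[0]}"
        )
    adj = _typed_adjacency(g)
    out: list[tuple[str, ...]] = []

    def walk(prefix: list[str], step: int) -> None:
        if step == len(schema.relations):
            out.append(tuple(prefix))
            return
        key = (schema.relations[step], schema.types[step + 1])
        for nxt in adj.get(key, {}).get(prefix[-1], []):
            prefix.append(nxt)
            walk(prefix, step + 1)
            prefix.pop()

    walk([anchor], 0)
    return out


def metapath_neighbors(g: HeteroGraph, schema: MetapathSchema, node: str) -> set[str]:
    """Endpoints of all instances anchored at ``node``, plus the node itself."""
    return {inst[-1] for inst in enumerate_instances(g, schema, node)} | {node}


def schema_adjacency(g: HeteroGraph, schema: MetapathSchema) -> sp.csr_matrix:
    """Anchor-by-anchor walk-count matrix: entry (i, j) counts the schema
    instances from anchor i ending at anchor j.

    Computed as the ordered product of binarized step (bi)adjacency
    matrices, which equals the walk count under walk semantics.
    """
    mats = []
    for (a, b), rname in zip(zip(schema.types, schema.types[1:]), schema.relations):
        rel = g.registry[rname]
        B = g.biadjacency(rname)
        B = (B != 0).astype(float)
        if (rel.src, rel.dst) == (a, b) or rel.symmetric:
            mats.append(B)
        else:
            mats.append(B.T)
    prod = mats[0]
    for m in mats[1:]:
        prod = prod @ m
    return sp.csr_matrix(prod)


def metapath_adjacencies(
    g: HeteroGraph, schemas: list[MetapathSchema]
) -> list[tuple[MetapathSchema, sp.csr_matrix]]:
    """Walk-count matrices for a schema list, skipping schemas that need a
    relation with no edges (logged once per schema)."""
    out = []
    for schema in schemas:
        if any(g.n_edges(r) == 0 for r in schema.relations):
            missing = [r for r in schema.relations if g.n_edges(r) == 0]
            logger.warning(
                "schema %s skipped: no edges for relation(s) %s", schema.name, missing
            )
            continue
        out.append((schema, schema_adjacency(g, schema)))
    return out


# -- metapath-level attention ---------------------------------------------


class EmptySchemasError(GraphError):
    """Every candidate schema has zero instances for every anchor."""


def pooled_terminal_features(
    A: sp.csr_matrix, anchor_features: ad.Tensor, weighted: bool = True
) -> ad.Tensor:
    """Mean feature of the instance endpoints reachable from each anchor.

    With ``weighted`` (default) the mean is weighted by instance
    multiplicity — a neighbor reached by several walks counts several
    times; otherwise the count matrix is binarized first.
    """
    W = A.astype(float)
    if not weighted:
        W = (W != 0).astype(float)
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    inv = np.where(rowsum > 0, 1.0 / np.where(rowsum > 0, rowsum, 1.0), 0.0)
    P = sp.diags(inv) @ W
    return sparse_matmul(P, anchor_features)


def sparse_matmul(A: sp.spmatrix, x: ad.Tensor) -> ad.Tensor:
    """Constant sparse matrix times a differentiable dense tensor."""
    x = ad.as_tensor(x)
    A = sp.csr_matrix(A)
    out = ad.Tensor(A @ x.data, True, (x,))
    out._backward = lambda g: x._accumulate(A.T @ g)
    return out


def _cosine_rows(a: ad.Tensor, b: ad.Tensor, eps: float = 1e-12) -> ad.Tensor:
    dot = (a * b).sum(axis=-1)
    na = ad.sqrt((a * a).sum(axis=-1) + eps)
    nb = ad.sqrt((b * b).sum(axis=-1) + eps)
    return dot / (na * nb)


def schema_attention(
    anchor_features: ad.Tensor,
    pooled_features: list[ad.Tensor],
    nonempty: np.ndarray,
    schema_embeddings: ad.Tensor,
    attn_weight: ad.Tensor,
    attn_bias: ad.Tensor,
) -> ad.Tensor:
    """Per-anchor attention weights over metapath schemas.

    The preliminary weight of schema s at anchor v is the cosine between
    the anchor's features and the schema-pooled terminal features; the
    final weight is a softmax (over schemas) of a learned affine map of
    ``[preliminary weight (+) schema embedding]``. Schemas with zero
    instances at an anchor are masked out and receive weight exactly 0
    after renormalization.

    Parameters
    ----------
    anchor_features : (n, d)
    pooled_features : list of S tensors (n, d)
    nonempty : bool array (n, S) — True where the schema has >= 1 instance
    schema_embeddings : (S, e)
    attn_weight : (1 + e,)
    attn_bias : scalar

    Returns
    -------
    (n, S) tensor of weights; rows sum to 1 over the unmasked schemas.
    """
    nonempty = np.asarray(nonempty, dtype=bool)
    if not nonempty.any():
        raise EmptySchemasError("every schema is empty for every anchor")
    cos = ad.stack(
        [_cosine_rows(anchor_features, p) for p in pooled_features], axis=1
    )  # (n, S)
    sch_term = schema_embeddings @ attn_weight[1:]  # (S,)
    logits = cos * attn_weight[0:1] + sch_term.reshape(1, -1) + attn_bias  # (n, S)
    # masked softmax: exp is multiplied by the mask so empty schemas are 0
    shift = ad.Tensor(np.max(logits.data, axis=1, keepdims=True))
    e = ad.exp(logits - shift) * ad.Tensor(nonempty.astype(float))
    denom = e.sum(axis=1, keepdims=True)
    safe = denom + ad.Tensor((denom.data == 0).astype(float))
    return e / safe
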