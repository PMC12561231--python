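"""Heterogeneous graph data model and edge-list I/O.

The graph couples four node types — Herb (H), Efficacy (E), Ingredient (I)
and Target (T) — through typed relations: herb-ingredient (H-I),
herb-efficacy (H-E), ingredient-target (I-T), herb-herb (H-H),
target-target (T-T) and the herb-target (H-T) links being predicted.
Symmetric relations (H-H, T-T, and the optional ingredient-similarity
relation I-I) store each undirected edge once; they are expanded to both
directions at message-passing time so that attention softmaxes are not
double-counted.

Node ids are strings; each type assigns contiguous integer indices in
insertion (manifest) order, which fixes the row/column semantics of every
matrix built downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

NODE_TYPES = ("H", "E", "I", "T")


class GraphError(Exception):
    """Base error for graph construction and lookup problems."""


class SchemaError(GraphError):
    """An edge or query violates the declared relation schema."""


class ValidationError(GraphError):
    """Structural invariant violated (duplicate edge, bad weight, ...)."""


@dataclass(frozen=True)
class RelationType:
    """A typed edge class: name, endpoint node types, symmetry flag."""

    name: str
    src: str
    dst: str
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.src not in NODE_TYPES or self.dst not in NODE_TYPES:
            raise SchemaError(f"unknown node type in relation {self.name!r}")
        if self.symmetric and self.src != self.dst:
            raise SchemaError(f"symmetric relation {self.name!r} must join one type")


def default_registry(include_ingredient_similarity: bool = True) -> dict[str, RelationType]:
    """The six relations of the herb-target graph, keyed by name.

    ``I-I`` is an optional similarity relation (built the same way as H-H);
    it is registered so that metapath schemas traversing two adjacent
    ingredients can be expressed, but graphs need not contain such edges.
    """
    rels = [
        RelationType("H-I", "H", "I"),
        RelationType("H-E", "H", "E"),
        RelationType("I-T", "I", "T"),
        RelationType("H-H", "H", "H", symmetric=True),
        RelationType("T-T", "T", "T", symmetric=True),
        RelationType("H-T", "H", "T"),
    ]
    if include_ingredient_similarity:
        rels.append(RelationType("I-I", "I", "I", symmetric=True))
    return {r.name: r for r in rels}


@dataclass
class HeteroGraph:
    """Typed node sets plus typed weighted edge lists.

    ``nodes`` maps node type to an ordered id list; ``edges`` maps relation
    name to a list of ``(src_id, dst_id, weight)`` triples. Weights default
    to 1.0; similarity-derived edges carry their similarity as weight.
    """

    registry: dict[str, RelationType] = field(default_factory=default_registry)
    nodes: dict[str, list[str]] = field(default_factory=lambda: {t: [] for t in NODE_TYPES})
    edges: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in NODE_TYPES:
            self.nodes.setdefault(t, [])
        self._index: dict[str, dict[str, int]] = {
            t: {n: i for i, n in enumerate(ids)} for t, ids in self.nodes.items()
        }
        self._edge_keys: dict[str, set[tuple[str, str]]] = {
            r: {self._canon(self.registry[r], s, d) for s, d, _ in es}
            for r, es in self.edges.items()
        }

    # -- nodes -----------------------------------------------------------

    def add_node(self, node_type: str, node_id: str) -> int:
        if node_type not in NODE_TYPES:
            raise SchemaError(f"unknown node type {node_type!r}")
        idx = self._index[node_type].get(node_id)
        if idx is None:
            idx = len(self.nodes[node_type])
            self.nodes[node_type].append(node_id)
            self._index[node_type][node_id] = idx
        return idx

    def has_node(self, node_type: str, node_id: str) -> bool:
        return node_id in self._index.get(node_type, {})

    def node_index(self, node_type: str, node_id: str) -> int:
        try:
            return self._index[node_type][node_id]
        except KeyError:
            raise GraphError(f"unknown {node_type} node {node_id!r}") from None

    def n_nodes(self, node_type: str) -> int:
        return len(self.nodes[node_type])

    def type_of(self, node_id: str) -> str:
        """Node type of an id, searching all four type namespaces."""
        hits = [t for t in NODE_TYPES if node_id in self._index[t]]
        if not hits:
            raise GraphError(f"unknown node {node_id!r}")
        if len(hits) > 1:
            raise GraphError(f"node id {node_id!r} is ambiguous across types {hits}")
        return hits[0]

    # -- edges -----------------------------------------------------------

    @staticmethod
    def _canon(rel: RelationType, src: str, dst: str) -> tuple[str, str]:
        # symmetric edges are stored once; key them orientation-free
        if rel.symmetric and dst < src:
            return dst, src
        return src, dst

    def add_edge(
        self,
        relation: str,
        src: str,
        dst: str,
        weight: float = 1.0,
        *,
        materialize: bool = True,
    ) -> None:
        rel = self.registry.get(relation)
        if rel is None:
            raise SchemaError(f"relation {relation!r} not in registry")
        for t, n in ((rel.src, src), (rel.dst, dst)):
            if not self.has_node(t, n):
                if not materialize:
                    raise SchemaError(f"{n!r} is not a declared {t} node (relation {relation})")
                # an id already claimed by a different type cannot be reused
                for other in NODE_TYPES:
                    if other != t and self.has_node(other, n):
                        raise SchemaError(
                            f"{n!r} is a {other} node, not a {t} node (relation {relation})"
                        )
                self.add_node(t, n)
        if not np.isfinite(weight) or not (0.0 <= weight <= 1.0):
            raise ValidationError(f"edge weight {weight} outside [0, 1]")
        key = self._canon(rel, src, dst)
        seen = self._edge_keys.setdefault(relation, set())
        if key in seen:
            raise ValidationError(f"duplicate edge ({relation}, {src}, {dst})")
        seen.add(key)
        self.edges.setdefault(relation, []).append((src, dst, float(weight)))

    def n_edges(self, relation: str | None = None) -> int:
        if relation is not None:
            return len(self.edges.get(relation, []))
        return sum(len(es) for es in self.edges.values())

    def degree(self, node: str, relation: str) -> int:
        """Number of edges of ``relation`` incident to ``node``.

        For symmetric relations the count is orientation-free, so both
        endpoints of a stored edge see it.
        """
        rel = self.registry.get(relation)
        if rel is None:
            raise SchemaError(f"relation {relation!r} not in registry")
        self.type_of(node)  # raises on unknown node
        count = 0
        for s, d, _ in self.edges.get(relation, []):
            if s == node and self.has_node(rel.src, node):
                count += 1
            elif d == node and self.has_node(rel.dst, node):
                count += 1
        return count

    # -- matrix views ----------------------------------------------------

    def biadjacency(self, relation: str) -> sp.csr_matrix:
        """Weighted (n_src x n_dst) matrix of one relation.

        For symmetric relations the square matrix is symmetrized (each
        stored edge appears in both orientations).
        """
        rel = self.registry[relation]
        n_src, n_dst = self.n_nodes(rel.src), self.n_nodes(rel.dst)
        rows, cols, vals = [], [], []
        for s, d, w in self.edges.get(relation, []):
            i, j = self._index[rel.src][s], self._index[rel.dst][d]
            rows.append(i)
            cols.append(j)
            vals.append(w)
            if rel.symmetric and i != j:
                rows.append(j)
                cols.append(i)
                vals.append(w)
        return sp.csr_matrix(
            (np.asarray(vals, dtype=float), (rows, cols)), shape=(n_src, n_dst)
        )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Re-check every structural invariant; raise on the first breach."""
        for t, ids in self.nodes.items():
            if len(ids) != len(set(ids)):
                raise ValidationError(f"duplicate node ids within type {t}")
        for r, es in self.edges.items():
            rel = self.registry.get(r)
            if rel is None:
                raise SchemaError(f"edges under unregistered relation {r!r}")
            keys = set()
            for s, d, w in es:
                if not self.has_node(rel.src, s) or not self.has_node(rel.dst, d):
                    raise SchemaError(f"edge ({r}, {s}, {d}) has an endpoint of the wrong type")
                if not (0.0 <= w <= 1.0):
                    raise ValidationError(f"edge ({r}, {s}, {d}) weight {w} outside [0, 1]")
                key = self._canon(rel, s, d)
                if key in keys:
                    raise ValidationError(f"duplicate edge ({r}, {s}, {d})")
                keys.add(key)


# -- I/O ------------------------------------------------------------------


def load_edge_lists(
    manifest: dict[str, str | Path],
    registry: dict[str, RelationType] | None = None,
    node_manifest: dict[str, list[str]] | None = None,
) -> HeteroGraph:
    """Build a validated :class:`HeteroGraph` from per-relation TSV files.

    Each file has a header ``src<TAB>dst[<TAB>weight]``. Unknown nodes are
    materialized from edges unless ``node_manifest`` is given, in which case
    every endpoint must be declared under the relation's endpoint type.
    """
    registry = registry if registry is not None else default_registry()
    g = HeteroGraph(registry=registry)
    materialize = node_manifest is None
    if node_manifest is not None:
        for t, ids in node_manifest.items():
            if t not in NODE_TYPES:
                raise SchemaError(f"unknown node type {t!r} in node manifest")
            for n in ids:
                g.add_node(t, n)
    for relation, path in manifest.items():
        if relation not in registry:
            raise SchemaError(f"relation {relation!r} not in registry")
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None:
                continue  # empty file -> no edges for this relation
            for row in reader:
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) == 2:
                    src, dst = row
                    w = 1.0
                elif len(row) == 3:
                    src, dst = row[0], row[1]
                    w = float(row[2])
                else:
                    raise ValidationError(f"{path}: malformed row {row!r}")
                g.add_edge(relation, src.strip(), dst.strip(), w, materialize=materialize)
    g.validate()
    return g


def write_edge_lists(g: HeteroGraph, out_dir: str | Path) -> dict[str, Path]:
    """Write one TSV per relation (only relations with edges); return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for relation, es in g.edges.items():
        path = out_dir / f"{relation}.tsv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["src", "dst", "weight"])
            for s, d, w in es:
                writer.writerow([s, d, repr(float(w))])
        paths[relation] = path
    return paths


def write_node_manifest(g: HeteroGraph, path: str | Path) -> Path:
    import json

    path = Path(path)
    path.write_text(json.dumps({t: ids for t, ids in g.nodes.items()}, indent=1))
    return path
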