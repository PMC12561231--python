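"""Herb-target representation learning.

The network embeds every node of the heterogeneous graph and distills the
embeddings into an attention-enhanced herb-target relation matrix. One
forward pass runs:

1. relation-level attention message passing — for every edge type r, a
   per-edge attention weight ``alpha_{r,u->v} = softmax_u LeakyReLU(
   a_r^T [W_r h_u || W_r h_v])`` and messages ``W_r h_u + e_r`` summed over
   all relations (metapath-derived auxiliary relations included);
2. skip-connected depth — shallow layers use dense connectivity (each
   layer's input concatenates all preceding outputs), deeper layers use
   residual graph convolutions with symmetric degree normalization
   ``1/sqrt(deg_i deg_j)``;
3. cross-hierarchical attention pooling — multi-head attention over the
   per-layer embeddings (each token augmented with a per-layer
   meta-relation embedding) yields the final node representation;
4. meta-relational scoring — softmax weights over learned meta-relation
   prototypes combine per-channel bilinear sigmoid scores into the
   N x M herb-target relation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from . import metapath as mp
from .autodiff import Parameter, Tensor
from .graph import NODE_TYPES, HeteroGraph
from .similarity import incidence_matrix


@dataclass
class RepresentationConfig:
    """Architecture hyperparameters.

    Defaults follow the reference setting (node embeddings of 256, output
    embeddings of 64, hidden size 64); desk-scale experiments shrink them.
    """

    node_dim: int = 256
    hidden_dim: int = 64
    out_dim: int = 64
    layers: int = 4
    k_dense: int = 2  # dense-connectivity depth; residual beyond
    heads: int = 4
    n_meta_relations: int = 3
    rel_emb_dim: int = 16  # per-layer meta-relation embedding in pooling tokens
    schema_emb_dim: int = 8
    proto_dim: int = 16
    leaky_slope: float = 0.2
    feature_init: str = "embedding"  # or "incidence"
    freeze_features: bool = False  # keep initial node features fixed
    init_scheme: str = "xavier"  # or "identity" (near-identity read-out path)
    score_form: str = "full"  # or "diag": diagonal bilinear score transforms
    metapath_weighting: str = "count"  # instance multiplicity up-weights neighbors
    use_metapaths: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.k_dense <= self.layers):
            raise ValueError("need 1 <= k_dense <= layers")
        if self.out_dim % self.heads:
            raise ValueError("out_dim must be divisible by heads")


# -- graph tensorization --------------------------------------------------


@dataclass
class GraphTensors:
    """Static index structures for one graph: global node indexing, per-
    relation edge arrays (both directions), the normalized union adjacency
    for residual layers, and per-anchor metapath walk-count matrices."""

    offsets: dict[str, int]
    n_nodes: int
    relations: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # src, dst, logw
    adj_norm: sp.csr_matrix
    metapaths: dict[str, list[tuple[mp.MetapathSchema, sp.csr_matrix]]]
    node_ids: list[str] = field(default_factory=list)
    # per anchor type: row-normalized schema matrices + anchor-by-schema
    # nonempty mask, precomputed once (they are static per graph)
    metapath_norm: dict[str, tuple[list[sp.csr_matrix], np.ndarray]] = field(
        default_factory=dict
    )


def build_graph_tensors(
    g: HeteroGraph, config: RepresentationConfig, exclude_relations: tuple[str, ...] = ()
) -> GraphTensors:
    offsets, total = {}, 0
    node_ids: list[str] = []
    for t in NODE_TYPES:
        offsets[t] = total
        total += g.n_nodes(t)
        node_ids.extend(g.nodes[t])

    relations: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    rows, cols = [], []
    for rname, es in g.edges.items():
        if rname in exclude_relations or not es:
            continue
        rel = g.registry[rname]
        src, dst, w = [], [], []
        for s, d, weight in es:
            i = offsets[rel.src] + g.node_index(rel.src, s)
            j = offsets[rel.dst] + g.node_index(rel.dst, d)
            # messages flow in both directions of every relation
            src.extend([i, j])
            dst.extend([j, i])
            w.extend([weight, weight])
            rows.extend([i, j])
            cols.extend([j, i])
        relations[rname] = (
            np.asarray(src, dtype=np.intp),
            np.asarray(dst, dtype=np.intp),
            np.log(np.maximum(np.asarray(w, dtype=float), 1e-12)),
        )

    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(total, total)
    )
    A.data[:] = 1.0  # parallel edges across relations collapse to 1
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1.0)), 0.0)
    D = sp.diags(inv_sqrt)
    adj_norm = sp.csr_matrix(D @ A @ D)

    metapaths: dict[str, list] = {}
    metapath_norm: dict[str, tuple[list, np.ndarray]] = {}
    if config.use_metapaths:
        weighted = config.metapath_weighting == "count"
        for t in ("H", "T"):
            if g.n_nodes(t) == 0:
                continue
            pairs = mp.metapath_adjacencies(g, mp.default_schemas(t, g.registry))
            metapaths[t] = pairs
            if not pairs:
                continue
            norms, masks = [], []
            for _, A in pairs:
                W = A.astype(float) if weighted else (A != 0).astype(float)
                rowsum = np.asarray(W.sum(axis=1)).ravel()
                inv = np.where(rowsum > 0, 1.0 / np.where(rowsum > 0, rowsum, 1.0), 0.0)
                norms.append(sp.csr_matrix(sp.diags(inv) @ W))
                masks.append(rowsum > 0)
            metapath_norm[t] = (norms, np.stack(masks, axis=1))

    return GraphTensors(
        offsets=offsets,
        n_nodes=total,
        relations=relations,
        adj_norm=adj_norm,
        metapaths=metapaths,
        node_ids=node_ids,
        metapath_norm=metapath_norm,
    )


# -- parameters -----------------------------------------------------------


class ModelParameters:
    """Every trainable weight of the representation network."""

    def __init__(
        self,
        g: HeteroGraph,
        tensors: GraphTensors,
        config: RepresentationConfig,
        rng: np.random.Generator,
    ):
        self.config = config
        d = config.node_dim
        xav = lambda *shape: ad.xavier_uniform(rng, shape)
        identity = config.init_scheme == "identity"
        if not identity and config.init_scheme != "xavier":
            raise ValueError(f"unknown init_scheme {config.init_scheme!r}")

        def near_eye(a: int, b: int) -> np.ndarray:
            # rectangular identity with a whisper of noise: the layer starts
            # as a pass-through and learns a refinement on top of it
            return np.eye(a, b) + 0.02 * rng.normal(size=(a, b))

        self.node_features = Parameter(self._init_features(g, tensors, config, rng), "X0")

        self.rel_attn: dict[str, Parameter] = {}
        self.rel_transform: dict[tuple[str, int], Parameter] = {}
        self.rel_feature: dict[tuple[str, int], Parameter] = {}
        for rname in tensors.relations:
            self.rel_attn[rname] = Parameter(xav(2 * d) * 0.1, f"a[{rname}]")
            for l in range(config.k_dense):
                self.rel_transform[(rname, l)] = Parameter(xav(d, d), f"W[{rname},{l}]")
                self.rel_feature[(rname, l)] = Parameter(np.zeros(d), f"e[{rname},{l}]")

        # metapath attention + auxiliary propagation, per anchor type
        self.schema_emb: dict[str, Parameter] = {}
        self.schema_attn_w: dict[str, Parameter] = {}
        self.schema_attn_b: dict[str, Parameter] = {}
        self.meta_transform: dict[tuple[str, int], Parameter] = {}
        for t, pairs in tensors.metapaths.items():
            S = len(pairs)
            if S == 0:
                continue
            self.schema_emb[t] = Parameter(xav(S, config.schema_emb_dim), f"schema_emb[{t}]")
            self.schema_attn_w[t] = Parameter(xav(1 + config.schema_emb_dim) * 0.1, f"schema_w[{t}]")
            self.schema_attn_b[t] = Parameter(np.zeros(1), f"schema_b[{t}]")
            for l in range(config.k_dense):
                self.meta_transform[(t, l)] = Parameter(xav(d, d), f"W_meta[{t},{l}]")

        # update + dense combination per shallow layer
        self.update_W = [Parameter(xav(d, d), f"W_upd[{l}]") for l in range(config.k_dense)]
        self.update_b = [Parameter(np.zeros(d), f"b_upd[{l}]") for l in range(config.k_dense)]
        self.dense_W = []
        for l in range(config.k_dense):
            if identity:
                # pass the previous layer through; feed the fresh aggregate in
                # at reduced gain so message passing perturbs, not replaces
                blocks = [np.zeros((d, d)) for _ in range(l + 2)]
                blocks[l] = np.eye(d)
                blocks[-1] = 0.2 * xav(d, d)
                W = np.vstack(blocks)
            else:
                W = xav((l + 2) * d, d)
            self.dense_W.append(Parameter(W, f"W_dense[{l}]"))
        self.dense_b = [Parameter(np.zeros(d), f"b_dense[{l}]") for l in range(config.k_dense)]

        # residual layers beyond k_dense
        n_res = config.layers - config.k_dense
        res_gain = 0.2 if identity else 1.0
        self.res_W = [Parameter(res_gain * xav(d, d), f"W_res[{l}]") for l in range(n_res)]

        # cross-hierarchical attention pooling
        L, r_dim, out = config.layers, config.rel_emb_dim, config.out_dim
        dk = out // config.heads
        self.layer_rel_emb = Parameter(xav(L, r_dim), "r_phi")
        if identity:
            # queries/keys start small (near-uniform token attention) and
            # the value/output path starts as a pass-through, so the pooled
            # embedding begins as roughly the mean of the layer embeddings
            self.W_Q = Parameter(0.2 * xav(d + r_dim, config.heads * dk), "W_Q")
            self.W_K = Parameter(0.2 * xav(d + r_dim, config.heads * dk), "W_K")
            self.W_V = Parameter(near_eye(d, config.heads * dk), "W_V")
            self.W_O = Parameter(near_eye(config.heads * dk, out), "W_O")
        else:
            self.W_Q = Parameter(xav(d + r_dim, config.heads * dk), "W_Q")
            self.W_K = Parameter(xav(d + r_dim, config.heads * dk), "W_K")
            self.W_V = Parameter(xav(d, config.heads * dk), "W_V")
            self.W_O = Parameter(xav(config.heads * dk, out), "W_O")
        self.b_O = Parameter(np.zeros(out), "b_O")

        # meta-relational relation-matrix channels
        P = config.n_meta_relations
        self.prototypes = Parameter(xav(P, config.proto_dim), "mu_phi")
        self.meta_attn_w = Parameter(xav(config.proto_dim + out) * 0.1, "w_beta")
        # the bilinear score transforms start at (or near) zero: an
        # untrained model scores every pair 0.5 — no ranking skill; the
        # herb-target alignment must come from supervision. The "diag" form
        # restricts each transform to a learned diagonal, the classic
        # low-parameter bilinear used when supervision is scarce; on
        # features embedded in one shared space the optimal alignment lies
        # inside that span.
        if config.score_form == "diag":
            self.score_diag = Parameter(np.zeros((P, out)), "w_phi_diag")
            self.score_W = None
        elif config.score_form == "full":
            self.score_diag = None
            self.score_W = Parameter(0.01 * xav(P, out, out), "W_phi")
        else:
            raise ValueError(f"unknown score_form {config.score_form!r}")
        # per-channel offset inside the sigmoid: without it, imbalanced
        # supervision forces the bilinear direction itself to carry the
        # negative base rate, which distorts (and can invert) the ranking
        self.score_bias = Parameter(np.zeros(P), "b_phi")

    @staticmethod
    def _init_features(
        g: HeteroGraph,
        tensors: GraphTensors,
        config: RepresentationConfig,
        rng: np.random.Generator,
    ) -> np.ndarray:
        d = config.node_dim
        X = rng.normal(0.0, 0.1, size=(tensors.n_nodes, d))
        if config.feature_init == "incidence":
            # all four types are embedded in one shared ingredient feature
            # space: ingredient i maps to a seeded random projection row
            # P[i]; a herb is the sum of its ingredients' vectors, a target
            # the sum of its ingredients' vectors, an efficacy the mean of
            # its herbs' vectors. Inner products between herb and target
            # features then approximate shared-ingredient path counts, so
            # the bilinear relation matrix starts from structural signal
            # instead of noise.
            n_i = g.n_nodes("I")
            if n_i and g.n_edges("H-I") and g.n_edges("I-T"):
                P = rng.normal(0.0, 1.0 / np.sqrt(d), (n_i, d))
                HI = incidence_matrix(g, "H", "I", "H-I")
                TI = incidence_matrix(g, "T", "I", "I-T")
                X[tensors.offsets["I"] : tensors.offsets["I"] + n_i] = P
                off_h = tensors.offsets["H"]
                X[off_h : off_h + HI.shape[0]] = HI @ P
                off_t = tensors.offsets["T"]
                X[off_t : off_t + TI.shape[0]] = TI @ P
                if g.n_nodes("E") and g.n_edges("H-E"):
                    EH = incidence_matrix(g, "E", "H", "H-E")
                    off_e = tensors.offsets["E"]
                    X[off_e : off_e + EH.shape[0]] = (EH @ (HI @ P)) / np.maximum(
                        EH.sum(axis=1, keepdims=True), 1.0
                    )
        elif config.feature_init != "embedding":
            raise ValueError(f"unknown feature_init {config.feature_init!r}")
        return X

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = [] if self.config.freeze_features else [self.node_features]
        out += list(self.rel_attn.values())
        out += list(self.rel_transform.values())
        out += list(self.rel_feature.values())
        out += list(self.schema_emb.values())
        out += list(self.schema_attn_w.values())
        out += list(self.schema_attn_b.values())
        out += list(self.meta_transform.values())
        out += self.update_W + self.update_b + self.dense_W + self.dense_b + self.res_W
        out += [
            self.layer_rel_emb,
            self.W_Q,
            self.W_K,
            self.W_V,
            self.W_O,
            self.b_O,
            self.prototypes,
            self.meta_attn_w,
            self.score_diag if self.score_W is None else self.score_W,
            self.score_bias,
        ]
        return out


# -- operations -----------------------------------------------------------


def relation_attention(
    neighbors: Tensor, center: Tensor, a_r: Tensor, W_r: Tensor, slope: float = 0.2
) -> Tensor:
    """Attention weights of a center node over one relation neighborhood.

    ``alpha_u = softmax_u LeakyReLU(a_r^T [W_r h_u || W_r h_center])``;
    the returned vector sums to 1 over the neighbors.
    """
    neighbors = ad.as_tensor(neighbors)
    if neighbors.ndim != 2 or neighbors.shape[0] == 0:
        raise ValueError("need a non-empty (n, d) neighbor matrix")
    n = neighbors.shape[0]
    Wu = neighbors @ W_r  # (n, d)
    Wc = (center.reshape(1, -1) @ W_r).reshape(-1)  # (d,)
    WcT = ad.stack([Wc] * n, axis=0)
    logits = ad.leaky_relu(ad.concat([Wu, WcT], axis=1) @ a_r, slope)
    return ad.softmax(logits, axis=0)


def _edge_softmax_messages(
    X: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    logw: np.ndarray,
    a_r: Tensor,
    W_r: Tensor,
    e_r: Tensor,
    n_nodes: int,
    slope: float,
) -> Tensor:
    """Vectorized relation-attention aggregation for one relation."""
    H = X @ W_r  # (V, d)
    Hu = ad.gather_rows(H, src)
    Hv = ad.gather_rows(H, dst)
    logits = ad.leaky_relu(ad.concat([Hu, Hv], axis=1) @ a_r, slope) + Tensor(logw)
    alpha = ad.segment_softmax(logits, dst, n_nodes)  # (E,)
    msg = Hu + e_r.reshape(1, -1)  # phi_r(h_u, h_v, e_r) = W_r h_u + e_r
    return ad.segment_sum(alpha.reshape(-1, 1) * msg, dst, n_nodes)


def _metapath_messages(
    X: Tensor,
    tensors: GraphTensors,
    params: ModelParameters,
    layer: int,
) -> Tensor | None:
    """Auxiliary messages from metapath neighbors, weighted by instance
    count and metapath-level attention, scattered into the global matrix."""
    pieces: list[tuple[int, int, Tensor]] = []
    for t, pairs in tensors.metapaths.items():
        if not pairs or t not in params.schema_emb or t not in tensors.metapath_norm:
            continue
        off = tensors.offsets[t]
        n = pairs[0][1].shape[0]
        X_anchor = X[off : off + n]
        norms, nonempty = tensors.metapath_norm[t]
        if not nonempty.any():
            continue
        pooled = [mp.sparse_matmul(P, X_anchor) for P in norms]
        attn = mp.schema_attention(
            X_anchor,
            pooled,
            nonempty,
            params.schema_emb[t],
            params.schema_attn_w[t],
            params.schema_attn_b[t],
        )  # (n, S)
        XW = X_anchor @ params.meta_transform[(t, layer)]
        agg = None
        for s, P in enumerate(norms):
            neigh = mp.sparse_matmul(P, XW)  # (n, d)
            contrib = attn[:, s : s + 1] * neigh
            agg = contrib if agg is None else agg + contrib
        pieces.append((off, n, agg))
    if not pieces:
        return None
    rows = np.concatenate([np.arange(off, off + n) for off, n, _ in pieces])
    block = ad.concat([p for _, _, p in pieces], axis=0)
    return ad.segment_sum(block, rows, tensors.n_nodes)


def aggregate_messages(
    tensors: GraphTensors,
    X: Tensor,
    params: ModelParameters,
    layer: int,
) -> Tensor:
    """Sum of attention-weighted messages over every relation:
    ``m_v = sum_r sum_{u in N_r(v)} alpha_{r,u->v} (W_r^l h_u + e_r^l)``.

    Nodes with no neighbors in any relation receive a zero message.
    """
    config = params.config
    m: Tensor | None = None
    for rname, (src, dst, logw) in tensors.relations.items():
        part = _edge_softmax_messages(
            X,
            src,
            dst,
            logw,
            params.rel_attn[rname],
            params.rel_transform[(rname, layer)],
            params.rel_feature[(rname, layer)],
            tensors.n_nodes,
            config.leaky_slope,
        )
        m = part if m is None else m + part
    if config.use_metapaths:
        aux = _metapath_messages(X, tensors, params, layer)
        if aux is not None:
            m = aux if m is None else m + aux
    if m is None:
        m = Tensor(np.zeros_like(X.data))
    return m


def update_node(m: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Layer update ``h^l = ReLU(W^l m^l + b^l)``."""
    return ad.relu(m @ W + b.reshape(1, -1))


def dense_layer(history: list[Tensor], W: Tensor, b: Tensor) -> Tensor:
    """Dense skip connection: concatenate the whole layer history, then an
    affine map and ReLU."""
    if not history:
        raise ValueError("dense_layer needs at least one history entry")
    X = history[0] if len(history) == 1 else ad.concat(history, axis=1)
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"history dim {X.shape[1]} does not match W rows {W.shape[0]}")
    return ad.relu(X @ W + b.reshape(1, -1))


def res_layer(adj_norm: sp.csr_matrix, h: Tensor, W: Tensor) -> Tensor:
    """Residual graph convolution
    ``h_i^{l+1} = ReLU(sum_j (1/c_ij) W h_j + h_i)`` with
    ``c_ij = sqrt(deg_i deg_j)``; isolated nodes reduce to ``ReLU(h_i)``."""
    return ad.relu(mp.sparse_matmul(adj_norm, h @ W) + h)


def cross_layer_pool(
    layer_embs: list[Tensor],
    params: ModelParameters,
) -> Tensor:
    """Cross-hierarchical attention pooling over the L per-layer embeddings.

    Each token is ``h_v^l (+) r_phi^l``; scaled dot-product multi-head
    attention mixes the tokens, head outputs are averaged over tokens,
    concatenated, and affinely mapped to the output dimension.
    """
    config = params.config
    L = len(layer_embs)
    V = layer_embs[0].shape[0]
    heads = config.heads
    dk = config.out_dim // heads

    toks = []
    for l, h in enumerate(layer_embs):
        r = params.layer_rel_emb[l].reshape(1, -1)
        r_rep = ad.concat([r] * V, axis=0)  # broadcast layer embedding to nodes
        toks.append(ad.concat([h, r_rep], axis=1))
    T = ad.stack(toks, axis=1)  # (V, L, d + r_dim)
    Tv = ad.stack(layer_embs, axis=1)  # (V, L, d)

    def split_heads(x: Tensor) -> Tensor:
        return x.reshape(V, L, heads, dk).transpose(0, 2, 1, 3)  # (V, heads, L, dk)

    Q = split_heads(T @ params.W_Q)
    K = split_heads(T @ params.W_K)
    Vv = split_heads(Tv @ params.W_V)
    scores = (Q @ K.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))  # (V, heads, L, L)
    attn = ad.softmax(scores, axis=-1)
    mixed = attn @ Vv  # (V, heads, L, dk)
    pooled = mixed.mean(axis=2)  # (V, heads, dk)
    flat = pooled.reshape(V, heads * dk)
    return flat @ params.W_O + params.b_O.reshape(1, -1)


def metarelation_weights(
    prototypes: Tensor, global_context: Tensor, attn_w: Tensor
) -> Tensor:
    """Softmax weights over meta-relation channels:
    ``beta_phi = softmax_phi w^T [mu_phi (+) h_bar]``."""
    P = prototypes.shape[0]
    ctx = ad.stack([global_context] * P, axis=0)  # (P, out_dim)
    logits = ad.concat([prototypes, ctx], axis=1) @ attn_w
    return ad.softmax(logits, axis=0)


def relation_matrix(
    H_herb: Tensor,
    H_target: Tensor,
    beta: Tensor,
    score_W: Tensor,
    score_bias: Tensor | None = None,
) -> Tensor:
    """Attention-enhanced relation matrix
    ``M = sum_phi beta_phi sigmoid(H_herb W_phi H_target^T + b_phi)`` — a
    convex combination of per-channel bilinear sigmoid scores, entries in
    (0, 1).

    ``score_W`` is either a stack of full transforms (P, d, d) or of
    diagonals (P, d); the diagonal form scores
    ``sigmoid((H_herb * w_phi) H_target^T + b_phi)``. The per-channel
    offset ``b_phi`` (default 0) absorbs the base rate of imbalanced
    supervision.
    """
    if H_herb.shape[1] != score_W.shape[-1]:
        raise ValueError("embedding dim does not match score transform")
    out = None
    P = score_W.shape[0]
    for p in range(P):
        if score_W.ndim == 2:  # diagonal transform
            logits = (H_herb * score_W[p].reshape(1, -1)) @ H_target.T
        else:
            logits = H_herb @ score_W[p] @ H_target.T
        if score_bias is not None:
            logits = logits + score_bias[p].reshape(1, 1)
        term = beta[p].reshape(1, 1) * ad.sigmoid(logits)
        out = term if out is None else out + term
    return out


def forward_representation(
    tensors: GraphTensors, params: ModelParameters
) -> tuple[Tensor, Tensor, Tensor]:
    """Full representation pass: returns (H_herb, H_target, relation matrix)."""
    config = params.config
    X = params.node_features
    history: list[Tensor] = [X]
    for l in range(config.k_dense):
        m = aggregate_messages(tensors, history[-1], params, l)
        u = update_node(m, params.update_W[l], params.update_b[l])
        history.append(dense_layer(history + [u], params.dense_W[l], params.dense_b[l]))
    for l in range(config.layers - config.k_dense):
        history.append(res_layer(tensors.adj_norm, history[-1], params.res_W[l]))

    H_final = cross_layer_pool(history[1:], params)  # layers 1..L

    off_h, n_h = tensors.offsets["H"], 0
    off_t, n_t = tensors.offsets["T"], 0
    # node counts inferred from offsets order H, E, I, T
    order = list(NODE_TYPES)
    sizes = {}
    for i, t in enumerate(order):
        nxt = tensors.n_nodes if i == len(order) - 1 else tensors.offsets[order[i + 1]]
        sizes[t] = nxt - tensors.offsets[t]
    n_h, n_t = sizes["H"], sizes["T"]

    H_herb = H_final[off_h : off_h + n_h]
    H_target = H_final[off_t : off_t + n_t]

    h_bar = ad.concat([H_herb, H_target], axis=0).mean(axis=0)
    beta = metarelation_weights(params.prototypes, h_bar, params.meta_attn_w)
    score = params.score_diag if params.score_W is None else params.score_W
    M = relation_matrix(H_herb, H_target, beta, score, params.score_bias)
    return H_herb, H_target, M
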