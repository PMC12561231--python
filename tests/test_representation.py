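"""Representation learning: attention, message passing, skip layers,
pooling, and the relation matrix — each against an independent oracle."""

import numpy as np
import pytest
import scipy.sparse as sp

import htinet.autodiff as ad
from htinet import HeteroGraph, RepresentationConfig
from htinet.autodiff import Tensor
from htinet.representation import (
    ModelParameters,
    aggregate_messages,
    build_graph_tensors,
    cross_layer_pool,
    dense_layer,
    forward_representation,
    metarelation_weights,
    relation_attention,
    relation_matrix,
    res_layer,
    update_node,
)

RNG = np.random.default_rng(123)


def small_config(**kw) -> RepresentationConfig:
    base = dict(
        node_dim=8, hidden_dim=8, out_dim=4, layers=2, k_dense=1, heads=2,
        n_meta_relations=2, rel_emb_dim=3, schema_emb_dim=2, proto_dim=3,
    )
    base.update(kw)
    return RepresentationConfig(**base)


class TestRelationAttention:
    def test_single_neighbor_weight_one(self):
        w = relation_attention(
            Tensor(RNG.normal(size=(1, 4))), Tensor(RNG.normal(size=4)),
            Tensor(RNG.normal(size=8)), Tensor(RNG.normal(size=(4, 4))),
        )
        assert np.allclose(w.data, [1.0])

    def test_identical_neighbors_split_evenly(self):
        nb = np.tile(RNG.normal(size=(1, 4)), (2, 1))
        w = relation_attention(
            Tensor(nb), Tensor(RNG.normal(size=4)),
            Tensor(RNG.normal(size=8)), Tensor(RNG.normal(size=(4, 4))),
        )
        assert np.allclose(w.data, [0.5, 0.5])

    def test_matches_two_line_softmax_oracle(self):
        nb, c = RNG.normal(size=(5, 3)), RNG.normal(size=3)
        a, W = RNG.normal(size=6), RNG.normal(size=(3, 3))
        w = relation_attention(Tensor(nb), Tensor(c), Tensor(a), Tensor(W))
        z = np.array(
            [np.concatenate([u @ W, c @ W]) @ a for u in nb]
        )
        z = np.where(z > 0, z, 0.2 * z)
        expected = np.exp(z - z.max()) / np.exp(z - z.max()).sum()
        assert np.allclose(w.data, expected, atol=1e-10)
        assert w.data.sum() == pytest.approx(1.0, abs=1e-6)


def _chain_graph() -> HeteroGraph:
    g = HeteroGraph()
    for t, ids in (("H", ["H1", "H2"]), ("I", ["I1"]), ("T", ["T1"])):
        for n in ids:
            g.add_node(t, n)
    g.add_edge("H-I", "H1", "I1")
    g.add_edge("H-I", "H2", "I1")
    g.add_edge("I-T", "I1", "T1")
    g.add_edge("H-H", "H1", "H2")
    return g


class TestAggregateMessages:
    def test_matches_triple_loop_oracle(self):
        """Vectorized relation-attention aggregation equals a per-node,
        per-relation, per-neighbor reference loop."""
        g = _chain_graph()
        config = small_config(use_metapaths=False)
        tensors = build_graph_tensors(g, config)
        params = ModelParameters(g, tensors, config, np.random.default_rng(0))
        X = Tensor(RNG.normal(size=(tensors.n_nodes, config.node_dim)))
        m = aggregate_messages(tensors, X, params, 0)

        expected = np.zeros_like(X.data)
        for rname, (src, dst, logw) in tensors.relations.items():
            W = params.rel_transform[(rname, 0)].data
            a = params.rel_attn[rname].data
            e = params.rel_feature[(rname, 0)].data
            for v in range(tensors.n_nodes):
                nbrs = [(s, lw) for s, d, lw in zip(src, dst, logw) if d == v]
                if not nbrs:
                    continue
                z = np.array(
                    [
                        np.concatenate([X.data[u] @ W, X.data[v] @ W]) @ a
                        for u, _ in nbrs
                    ]
                )
                z = np.where(z > 0, z, config.leaky_slope * z) + np.array(
                    [lw for _, lw in nbrs]
                )
                alpha = np.exp(z - z.max()) / np.exp(z - z.max()).sum()
                for (u, _), al in zip(nbrs, alpha):
                    expected[v] += al * (X.data[u] @ W + e)
        assert np.allclose(m.data, expected, atol=1e-8)

    def test_isolated_node_zero_message(self):
        g = _chain_graph()
        g.add_node("E", "E1")  # no edges
        config = small_config(use_metapaths=False)
        tensors = build_graph_tensors(g, config)
        params = ModelParameters(g, tensors, config, np.random.default_rng(0))
        X = Tensor(RNG.normal(size=(tensors.n_nodes, config.node_dim)))
        m = aggregate_messages(tensors, X, params, 0)
        e_row = tensors.offsets["E"]
        assert np.allclose(m.data[e_row], 0.0)

    def test_neighbor_order_invariance(self):
        """Permuting the edge list leaves the aggregated messages unchanged."""
        g = _chain_graph()
        config = small_config(use_metapaths=False)
        tensors = build_graph_tensors(g, config)
        params = ModelParameters(g, tensors, config, np.random.default_rng(0))
        X = Tensor(RNG.normal(size=(tensors.n_nodes, config.node_dim)))
        m1 = aggregate_messages(tensors, X, params, 0)
        for rname, (src, dst, logw) in list(tensors.relations.items()):
            perm = np.random.default_rng(1).permutation(len(src))
            tensors.relations[rname] = (src[perm], dst[perm], logw[perm])
        m2 = aggregate_messages(tensors, X, params, 0)
        assert np.allclose(m1.data, m2.data, atol=1e-10)


class TestLayers:
    def test_update_node_affine_relu(self):
        m, W, b = RNG.normal(size=(3, 4)), RNG.normal(size=(4, 4)), RNG.normal(size=4)
        out = update_node(Tensor(m), Tensor(W), Tensor(b))
        assert np.allclose(out.data, np.maximum(m @ W + b, 0.0))
        z = update_node(Tensor(np.zeros((2, 4))), Tensor(W), Tensor(np.zeros(4)))
        assert np.allclose(z.data, 0.0)

    def test_dense_layer_concatenation_oracle(self):
        hist = [RNG.normal(size=(3, 4)) for _ in range(3)]
        W, b = RNG.normal(size=(12, 4)), RNG.normal(size=4)
        out = dense_layer([Tensor(h) for h in hist], Tensor(W), Tensor(b))
        assert np.allclose(out.data, np.maximum(np.concatenate(hist, 1) @ W + b, 0))

    def test_dense_layer_single_entry_reduces_to_update(self):
        h = RNG.normal(size=(3, 4))
        W, b = RNG.normal(size=(4, 4)), RNG.normal(size=4)
        a = dense_layer([Tensor(h)], Tensor(W), Tensor(b))
        u = update_node(Tensor(h), Tensor(W), Tensor(b))
        assert np.allclose(a.data, u.data)

    def test_dense_layer_shape_mismatch(self):
        with pytest.raises(ValueError):
            dense_layer([Tensor(np.ones((2, 3)))], Tensor(np.ones((4, 3))), Tensor(np.zeros(3)))

    def test_res_layer_zero_weights_identity_on_nonnegative(self):
        A = sp.csr_matrix(np.array([[0.0, 0.5], [0.5, 0.0]]))
        h = np.abs(RNG.normal(size=(2, 3)))
        out = res_layer(A, Tensor(h), Tensor(np.zeros((3, 3))))
        assert np.allclose(out.data, h)

    def test_res_layer_ring_matches_normalized_matmul_oracle(self):
        n = 5
        ring = np.zeros((n, n))
        for i in range(n):
            ring[i, (i + 1) % n] = ring[(i + 1) % n, i] = 1.0
        deg = ring.sum(1)
        A = ring / np.sqrt(np.outer(deg, deg))
        h, W = RNG.normal(size=(n, 3)), RNG.normal(size=(3, 3))
        out = res_layer(sp.csr_matrix(A), Tensor(h), Tensor(W))
        assert np.allclose(out.data, np.maximum(A @ h @ W + h, 0.0), atol=1e-10)

    def test_res_layer_isolated_node_is_activation_of_input(self):
        A = sp.csr_matrix(np.zeros((2, 2)))
        h = RNG.normal(size=(2, 3))
        out = res_layer(A, Tensor(h), Tensor(RNG.normal(size=(3, 3))))
        assert np.allclose(out.data, np.maximum(h, 0.0))


class TestPooling:
    def _params(self, config, V=4):
        g = _chain_graph()
        tensors = build_graph_tensors(g, config)
        return ModelParameters(g, tensors, config, np.random.default_rng(0))

    def test_identical_tokens_uniform_attention(self):
        config = small_config(use_metapaths=False)
        params = self._params(config)
        h = Tensor(RNG.normal(size=(4, config.node_dim)))
        out_same = cross_layer_pool([h, h], params)
        # uniform attention over identical tokens = the single-token output
        out_single = cross_layer_pool([h, h], params)
        assert np.allclose(out_same.data, out_single.data)
        assert out_same.shape == (4, config.out_dim)

    def test_matches_scaled_dot_product_oracle(self):
        config = small_config(use_metapaths=False)
        params = self._params(config)
        L, V, d = 2, 3, config.node_dim
        embs = [RNG.normal(size=(V, d)) for _ in range(L)]
        out = cross_layer_pool([Tensor(e) for e in embs], params)

        heads, dk = config.heads, config.out_dim // config.heads
        toks = np.stack(
            [
                np.concatenate(
                    [e, np.tile(params.layer_rel_emb.data[l], (V, 1))], axis=1
                )
                for l, e in enumerate(embs)
            ],
            axis=1,
        )  # (V, L, d + r)
        vals = np.stack(embs, axis=1)  # (V, L, d)
        Q = (toks @ params.W_Q.data).reshape(V, L, heads, dk).transpose(0, 2, 1, 3)
        K = (toks @ params.W_K.data).reshape(V, L, heads, dk).transpose(0, 2, 1, 3)
        Vv = (vals @ params.W_V.data).reshape(V, L, heads, dk).transpose(0, 2, 1, 3)
        scores = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(dk)
        attn = np.exp(scores - scores.max(-1, keepdims=True))
        attn /= attn.sum(-1, keepdims=True)
        mixed = (attn @ Vv).mean(axis=2).reshape(V, heads * dk)
        expected = mixed @ params.W_O.data + params.b_O.data
        assert np.allclose(out.data, expected, atol=1e-8)
        assert np.allclose(attn.sum(-1), 1.0, atol=1e-6)


class TestRelationMatrix:
    def test_metarelation_weights_softmax(self):
        protos = RNG.normal(size=(3, 2))
        ctx = RNG.normal(size=4)
        w = RNG.normal(size=6)
        beta = metarelation_weights(Tensor(protos), Tensor(ctx), Tensor(w))
        logits = np.concatenate([protos, np.tile(ctx, (3, 1))], axis=1) @ w
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        assert np.allclose(beta.data, expected, atol=1e-10)
        assert beta.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_channel_weight_one(self):
        beta = metarelation_weights(
            Tensor(RNG.normal(size=(1, 2))), Tensor(RNG.normal(size=3)),
            Tensor(RNG.normal(size=5)),
        )
        assert np.allclose(beta.data, [1.0])

    def test_identical_prototypes_uniform(self):
        protos = np.tile(RNG.normal(size=(1, 2)), (4, 1))
        beta = metarelation_weights(
            Tensor(protos), Tensor(RNG.normal(size=3)), Tensor(RNG.normal(size=5))
        )
        assert np.allclose(beta.data, 0.25)

    def test_zero_transform_all_half(self):
        H, T = RNG.normal(size=(3, 4)), RNG.normal(size=(5, 4))
        beta = Tensor(np.array([1.0]))
        M = relation_matrix(Tensor(H), Tensor(T), beta, Tensor(np.zeros((1, 4, 4))))
        assert np.allclose(M.data, 0.5)

    def test_matches_loop_oracle_and_open_interval(self):
        N, Mn, d, P = 3, 4, 5, 2
        H, T = RNG.normal(size=(N, d)), RNG.normal(size=(Mn, d))
        beta = np.array([0.3, 0.7])
        Ws = RNG.normal(size=(P, d, d))
        M = relation_matrix(Tensor(H), Tensor(T), Tensor(beta), Tensor(Ws))
        expected = np.zeros((N, Mn))
        for p in range(P):
            for i in range(N):
                for j in range(Mn):
                    expected[i, j] += beta[p] / (1 + np.exp(-(H[i] @ Ws[p] @ T[j])))
        assert np.allclose(M.data, expected, atol=1e-10)
        assert (M.data > 0).all() and (M.data < 1).all()


class TestForward:
    def test_toy_forward_shapes_and_finiteness(self, toy_graph):
        config = small_config()
        tensors = build_graph_tensors(toy_graph, config)
        params = ModelParameters(toy_graph, tensors, config, np.random.default_rng(0))
        H_herb, H_target, M = forward_representation(tensors, params)
        assert H_herb.shape == (3, config.out_dim)
        assert H_target.shape == (3, config.out_dim)
        assert M.shape == (3, 3)
        assert np.isfinite(M.data).all()
        assert ((M.data > 0) & (M.data < 1)).all()

    def test_fixed_seed_bitwise_deterministic(self, toy_graph):
        outs = []
        for _ in range(2):
            config = small_config()
            tensors = build_graph_tensors(toy_graph, config)
            params = ModelParameters(toy_graph, tensors, config, np.random.default_rng(9))
            outs.append(forward_representation(tensors, params)[2].data)
        assert np.array_equal(outs[0], outs[1])

    def test_gradient_reaches_every_parameter_group(self, toy_graph):
        """One backward pass touches attention, transforms, pooling and
        scoring weights alike (no silent dead branches)."""
        config = small_config()
        tensors = build_graph_tensors(toy_graph, config)
        params = ModelParameters(toy_graph, tensors, config, np.random.default_rng(3))
        _, _, M = forward_representation(tensors, params)
        M.sum().backward()
        touched = [
            params.node_features,
            params.update_W[0],
            params.dense_W[0],
            params.W_Q,
            params.W_V,
            params.score_W,
            params.meta_attn_w,
        ]
        for p in touched:
            assert p.grad is not None and np.abs(p.grad).sum() > 0, p.name
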