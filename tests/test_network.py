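"""GAT layer, decoders, and classifier against literal dense oracles.

The oracle implements the attention equations exactly as written —
explicit loops over nodes, heads, and neighborhoods — independent of
the vectorized implementation under test.
"""

import numpy as np
import pytest

from stguide._autograd import Tensor
from stguide.graph import ComposedGraph
from stguide.network import (
    NEG_SLOPE,
    Classifier,
    Encoder,
    GATLayer,
    SliceDecoder,
    attention_mask,
    decode_adjacency,
)
from stguide.preprocessing import SpotIndexMap


def dense_gat_oracle(H, adj, Ws, a_srcs, a_dsts, elu=True):
    """Literal loop implementation of the attention equations."""
    n = H.shape[0]
    Q = len(Ws)
    out = np.zeros((n, Ws[0].shape[1]))
    for i in range(n):
        neigh = [j for j in range(n) if adj[i, j] or j == i]
        acc = np.zeros(Ws[0].shape[1])
        for q in range(Q):
            Wh = H @ Ws[q]
            logits = {}
            for j in neigh:
                val = a_srcs[q] @ Wh[i] + a_dsts[q] @ Wh[j]
                logits[j] = val if val > 0 else NEG_SLOPE * val
            mx = max(logits.values())
            denom = sum(np.exp(v - mx) for v in logits.values())
            for j in neigh:
                alpha = np.exp(logits[j] - mx) / denom
                acc += alpha * Wh[j]
        acc /= Q
        out[i] = np.where(acc > 0, acc, np.expm1(acc)) if elu else acc
    return out


def _random_graph(rng, n, p=0.3):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = True
    edges = [(i, j, "spatial") for i in range(n) for j in range(i + 1, n) if adj[i, j]]
    imap = SpotIndexMap(slice_ids=("s",), sizes=(n,))
    return adj, ComposedGraph(n_nodes=n, edges=edges, index_map=imap)


class TestGATLayer:
    def test_identical_neighbor_features_give_uniform_attention(self, rng):
        adj, graph = _random_graph(rng, 8, p=0.5)
        layer = GATLayer(4, 3, n_heads=2, rng=rng)
        h = Tensor(np.tile(rng.normal(size=(1, 4)), (8, 1)))
        layer.forward(h, attention_mask(graph.adjacency))
        for attn in layer.last_attention:
            for i in range(8):
                neigh = attn[i] > 0
                np.testing.assert_allclose(
                    attn[i][neigh], 1.0 / neigh.sum(), atol=1e-12
                )

    def test_single_node_identity_weights_pass_through(self, rng):
        graph = ComposedGraph(
            n_nodes=1, edges=[], index_map=SpotIndexMap(("s",), (1,))
        )
        layer = GATLayer(3, 3, n_heads=1, rng=rng)
        layer.W[0].data = np.eye(3)
        x = rng.normal(size=(1, 3))
        out = layer.forward(Tensor(x), attention_mask(graph.adjacency), "none")
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_three_node_path_matches_hand_scalar_computation(self, rng):
        # path 0-1-2, 1-D features and weights: fully hand-checkable
        edges = [(0, 1, "spatial"), (1, 2, "spatial")]
        graph = ComposedGraph(3, edges, SpotIndexMap(("s",), (3,)))
        layer = GATLayer(1, 1, n_heads=1, rng=rng)
        layer.W[0].data = np.array([[2.0]])
        layer.a_src[0].data = np.array([1.0])
        layer.a_dst[0].data = np.array([0.5])
        h = np.array([[1.0], [2.0], [3.0]])
        out = layer.forward(Tensor(h), attention_mask(graph.adjacency), "none")
        oracle = dense_gat_oracle(
            h,
            graph.adjacency.toarray(),
            [layer.W[0].data],
            [layer.a_src[0].data],
            [layer.a_dst[0].data],
            elu=False,
        )
        np.testing.assert_allclose(out.data, oracle, atol=1e-12)

    @pytest.mark.parametrize("n,heads", [(10, 1), (25, 3), (50, 2)])
    def test_matches_literal_dense_oracle(self, rng, n, heads):
        adj, graph = _random_graph(rng, n)
        layer = GATLayer(6, 4, n_heads=heads, rng=rng)
        h = rng.normal(size=(n, 6))
        out = layer.forward(Tensor(h), attention_mask(graph.adjacency))
        oracle = dense_gat_oracle(
            h,
            adj,
            [w.data for w in layer.W],
            [a.data for a in layer.a_src],
            [a.data for a in layer.a_dst],
        )
        np.testing.assert_allclose(out.data, oracle, atol=1e-5)

    def test_attention_rows_sum_to_one(self, rng):
        adj, graph = _random_graph(rng, 20)
        layer = GATLayer(5, 4, n_heads=3, rng=rng)
        layer.forward(Tensor(rng.normal(size=(20, 5))), attention_mask(graph.adjacency))
        for attn in layer.last_attention:
            np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-6)


class TestEncoder:
    def test_zero_weights_give_zero_embedding(self, rng):
        adj, graph = _random_graph(rng, 6)
        enc = Encoder([4, 3, 2], n_heads=2, rng=rng)
        for layer in enc.layers:
            for w in layer.W:
                w.data[:] = 0.0
        out = enc.forward(Tensor(rng.normal(size=(6, 4))), attention_mask(graph.adjacency))
        np.testing.assert_allclose(out.data, 0.0)

    def test_permutation_equivariance(self, rng):
        adj, graph = _random_graph(rng, 12)
        enc = Encoder([5, 4, 3], n_heads=2, rng=rng)
        x = rng.normal(size=(12, 5))
        mask = attention_mask(graph.adjacency)
        base = enc.forward(Tensor(x), mask).data
        perm = rng.permutation(12)
        mask_p = mask[np.ix_(perm, perm)]
        out_p = enc.forward(Tensor(x[perm]), mask_p).data
        np.testing.assert_allclose(out_p, base[perm], atol=1e-10)

    def test_two_layer_composition_matches_oracle(self, rng):
        adj, graph = _random_graph(rng, 15)
        enc = Encoder([4, 6, 2], n_heads=2, rng=rng)
        x = rng.normal(size=(15, 4))
        out = enc.forward(Tensor(x), attention_mask(graph.adjacency)).data
        h1 = dense_gat_oracle(
            x,
            adj,
            [w.data for w in enc.layers[0].W],
            [a.data for a in enc.layers[0].a_src],
            [a.data for a in enc.layers[0].a_dst],
        )
        h2 = dense_gat_oracle(
            h1,
            adj,
            [w.data for w in enc.layers[1].W],
            [a.data for a in enc.layers[1].a_src],
            [a.data for a in enc.layers[1].a_dst],
            elu=False,
        )
        np.testing.assert_allclose(out, h2, atol=1e-5)

    def test_dimension_mismatch_errors(self, rng):
        adj, graph = _random_graph(rng, 5)
        enc = Encoder([4, 3, 2], n_heads=1, rng=rng)
        with pytest.raises(ValueError, match="features"):
            enc.forward(Tensor(rng.normal(size=(5, 7))), attention_mask(graph.adjacency))


class TestSliceDecoder:
    def test_identity_normalization_in_eval_mode(self, rng):
        dec = SliceDecoder(3, 2, rng)
        dec.running_mean[:] = 0.0
        dec.running_var[:] = 1.0 - 1e-5
        z = rng.normal(size=(4, 3))
        out = dec.forward(Tensor(z), mode="eval")
        np.testing.assert_allclose(out.data, z @ dec.W.data + dec.b.data, atol=1e-10)

    def test_zero_gamma_returns_beta(self, rng):
        dec = SliceDecoder(3, 2, rng)
        dec.gamma.data[:] = 0.0
        dec.beta.data[:] = [1.5, -2.0]
        out = dec.forward(Tensor(rng.normal(size=(5, 3))), mode="train")
        np.testing.assert_allclose(out.data, np.tile([1.5, -2.0], (5, 1)))

    def test_two_spot_one_gene_hand_arithmetic(self, rng):
        dec = SliceDecoder(1, 1, rng)
        dec.W.data = np.array([[2.0]])
        dec.b.data = np.array([1.0])
        dec.gamma.data = np.array([3.0])
        dec.beta.data = np.array([0.5])
        z = np.array([[1.0], [3.0]])
        # h = [3, 7]; mu = 5, var = 4 -> normalized [-1, 1] -> [-2.5, 3.5]
        out = dec.forward(Tensor(z), mode="train")
        expect = 3.0 * (np.array([[3.0], [7.0]]) - 5.0) / np.sqrt(4.0 + 1e-5) + 0.5
        np.testing.assert_allclose(out.data, expect, atol=1e-10)

    def test_single_spot_variance_guarded_by_eps(self, rng):
        dec = SliceDecoder(2, 3, rng)
        out = dec.forward(Tensor(rng.normal(size=(1, 2))), mode="train")
        assert np.all(np.isfinite(out.data))


class TestAdjacencyDecoder:
    def test_zero_embedding_gives_half_everywhere(self):
        out = decode_adjacency(Tensor(np.zeros((4, 3))))
        np.testing.assert_allclose(out.data, 0.5)

    def test_orthonormal_rows_closed_form(self):
        out = decode_adjacency(Tensor(np.eye(3)))
        expect = np.full((3, 3), 0.5)
        np.fill_diagonal(expect, 1 / (1 + np.exp(-1)))
        np.testing.assert_allclose(out.data, expect, atol=1e-12)

    def test_scaling_pushes_away_from_half(self, rng):
        z = rng.normal(size=(5, 3))
        a1 = decode_adjacency(Tensor(z)).data
        a2 = decode_adjacency(Tensor(2.0 * z)).data
        assert np.all(np.abs(a2 - 0.5) >= np.abs(a1 - 0.5) - 1e-12)


class TestClassifier:
    def test_zero_weights_uniform_probabilities(self, rng):
        clf = Classifier(4, 3, rng)
        clf.W.data[:] = 0.0
        out = clf.forward(Tensor(rng.normal(size=(6, 4))))
        np.testing.assert_allclose(out.data, 1.0 / 3.0)

    def test_large_weights_saturate_argmax(self, rng):
        clf = Classifier(2, 2, rng)
        clf.W.data = np.array([[50.0, -50.0], [-50.0, 50.0]])
        out = clf.forward(Tensor(np.array([[1.0, 0.0]])))
        np.testing.assert_allclose(out.data, [[1.0, 0.0]], atol=1e-20)

    def test_two_class_hand_softmax(self, rng):
        clf = Classifier(1, 2, rng)
        clf.W.data = np.array([[1.0, -1.0]])
        out = clf.forward(Tensor(np.array([[2.0]])))
        e = np.exp([2.0, -2.0])
        np.testing.assert_allclose(out.data, (e / e.sum())[None], atol=1e-12)

    def test_rows_are_simplex_vectors(self, rng):
        clf = Classifier(5, 4, rng)
        out = clf.forward(Tensor(rng.normal(size=(20, 5)) * 10))
        assert np.all(out.data >= 0)
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-6)


def test_state_dict_round_trip(rng):
    from stguide.network import StGuideNetwork

    net = StGuideNetwork(8, ["a", "b"], n_classes=3, hidden_dim=6, latent_dim=2, seed=1)
    state = net.state_dict()
    other = StGuideNetwork(8, ["a", "b"], n_classes=3, hidden_dim=6, latent_dim=2, seed=2)
    other.load_state_dict(state)
    for k, v in other.state_dict().items():
        np.testing.assert_array_equal(v, state[k])
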