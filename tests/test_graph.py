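"""Spatial k-NN, mutual-NN, and composed-graph construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stguide.datasets import MultiSliceDataset, SliceData
from stguide.graph import build_mnn_edges, build_spatial_edges, compose
from stguide.preprocessing import assemble_input


def brute_force_knn(points, i, k):
    """Indices of the k nearest other points, ties to lower index."""
    d = np.linalg.norm(points - points[i], axis=1)
    d[i] = np.inf
    idx = np.arange(len(points))
    return set(idx[np.lexsort((idx, d))][:k].tolist())


def brute_force_mnn(a, b, k):
    edges = set()
    for i in range(len(a)):
        da = np.linalg.norm(b - a[i], axis=1)
        idx = np.arange(len(b))
        nn_i = set(idx[np.lexsort((idx, da))][: min(k, len(b))].tolist())
        for j in nn_i:
            db = np.linalg.norm(a - b[j], axis=1)
            jdx = np.arange(len(a))
            nn_j = set(jdx[np.lexsort((jdx, db))][: min(k, len(a))].tolist())
            if i in nn_j:
                edges.add((i, j))
    return edges


class TestSpatialEdges:
    def test_two_spots_single_edge(self):
        assert build_spatial_edges(np.array([[0.0, 0.0], [1.0, 0.0]]), avg_k=1) == [
            (0, 1)
        ]

    def test_line_fixture_matches_hand_distances(self):
        # x = 0, 1, 2, 10: nearest of 10 is 2, symmetrized union has 3 edges
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [10.0, 0]])
        assert build_spatial_edges(coords, avg_k=1) == [(0, 1), (1, 2), (2, 3)]

    def test_grid_interior_spot_gets_rook_neighbors(self):
        rr, cc = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
        coords = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
        edges = build_spatial_edges(coords, avg_k=4)
        center = 12  # (row 2, col 2)
        neigh = {b for a, b in edges if a == center} | {
            a for a, b in edges if b == center
        }
        assert neigh == {7, 11, 13, 17}

    def test_small_slice_falls_back_to_complete_graph(self):
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        with pytest.warns(UserWarning, match="connecting to all"):
            edges = build_spatial_edges(coords, avg_k=5)
        assert edges == [(0, 1), (0, 2), (1, 2)]

    def test_average_degree_at_least_k(self, rng):
        coords = rng.normal(size=(40, 2))
        edges = build_spatial_edges(coords, avg_k=5)
        deg = np.zeros(40)
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
        assert deg.mean() >= 5
        assert deg.min() >= 5

    def test_matches_brute_force_union(self, rng):
        coords = rng.normal(size=(25, 2))
        edges = set(build_spatial_edges(coords, avg_k=3))
        expect = set()
        for i in range(25):
            for j in brute_force_knn(coords, i, 3):
                expect.add((min(i, j), max(i, j)))
        assert edges == expect


class TestMnnEdges:
    def test_identical_slices_identity_matching(self, rng):
        feat = rng.normal(size=(30, 5))
        edges = build_mnn_edges(feat, feat.copy(), k=1)
        assert edges == [(i, i) for i in range(30)]

    def test_single_spot_pair_always_matched(self, rng):
        a = rng.normal(size=(1, 4))
        b = rng.normal(size=(1, 4))
        assert build_mnn_edges(a, b, k=5) == [(0, 0)]

    def test_far_outlier_gets_no_edge(self):
        # a1 is far from every b; b spots mutually match a0
        a = np.array([[0.0, 0.0], [100.0, 100.0]])
        b = np.array([[0.1, 0.0], [0.0, 0.1]])
        edges = build_mnn_edges(a, b, k=1)
        assert all(src != 1 for src, _ in edges)

    def test_empty_matrix_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            assert build_mnn_edges(np.empty((0, 3)), np.ones((2, 3))) == []

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        na=st.integers(2, 12),
        nb=st.integers(2, 12),
        k=st.integers(1, 4),
        seed=st.integers(0, 10_000),
    )
    def test_mutuality_matches_brute_force(self, na, nb, k, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=(na, 3))
        b = r.normal(size=(nb, 3))
        assert set(build_mnn_edges(a, b, k=k)) == brute_force_mnn(a, b, k)


class TestCompose:
    def _graph(self, dataset, subset="all", **kw):
        genes = sorted(dataset.slices[0].gene_names)
        X, imap = assemble_input(dataset, genes, subset)
        return compose(dataset, X, imap, **kw)

    def test_single_reference_slice_has_only_spatial_edges(self, small_dataset):
        g = self._graph(small_dataset, "reference_only")
        assert g.edge_kinds()["mnn"] == 0
        assert g.edge_kinds()["spatial"] > 0

    def test_reference_only_excludes_query_nodes(self, small_dataset):
        g = self._graph(small_dataset, "reference_only")
        assert g.n_nodes == small_dataset.slices[0].n_spots

    def test_node_count_conservation(self, small_dataset):
        g = self._graph(small_dataset)
        assert g.n_nodes == sum(s.n_spots for s in small_dataset.slices)

    def test_adjacency_symmetric_zero_diagonal(self, small_dataset):
        a = self._graph(small_dataset).adjacency
        assert (a != a.T).nnz == 0
        assert a.diagonal().sum() == 0

    def test_identical_slices_contain_identity_mnn(self, rng):
        expr = rng.poisson(8.0, size=(16, 10)).astype(float) + 1
        coords = np.column_stack(
            [np.tile(np.arange(4), 4), np.repeat(np.arange(4), 4)]
        ).astype(float)
        genes = [f"g{j}" for j in range(10)]
        mk = lambda sid, role: SliceData(
            slice_id=sid,
            expression=expr.copy(),
            coords=coords.copy(),
            gene_names=genes,
            labels=np.array(["x"] * 16) if role == "reference" else None,
            role=role,
        )
        ds = MultiSliceDataset([mk("a", "reference"), mk("b", "query")])
        g = self._graph(ds, mnn_k=1)
        mnn = {(a_, b_) for a_, b_, kind in g.edges if kind == "mnn"}
        assert mnn == {(i, 16 + i) for i in range(16)}

    def test_mnn_edges_cross_slices_spatial_edges_within(self, small_dataset):
        g = self._graph(small_dataset)
        for a, b, kind in g.edges:
            same = g.index_map.locate(a)[0] == g.index_map.locate(b)[0]
            assert same == (kind == "spatial")

    def test_deterministic_edge_sets(self, small_dataset):
        g1 = self._graph(small_dataset)
        g2 = self._graph(small_dataset)
        assert g1.edges == g2.edges

    def test_tsv_round_trip(self, small_dataset, tmp_path):
        from stguide.graph import ComposedGraph

        g = self._graph(small_dataset)
        g.to_tsv(tmp_path / "edges.tsv")
        back = ComposedGraph.from_tsv(tmp_path / "edges.tsv", g.n_nodes, g.index_map)
        assert back.edges == g.edges
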