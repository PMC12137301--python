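"""Composed graphs over multi-slice spot sets.

Within each slice, spots are linked to their spatial k-nearest
neighbors (Euclidean distance in platform coordinates).  Across slices,
spots are linked when they are mutual nearest neighbors (MNN) in a
shared expression feature space; MNN edges bridge slice-specific batch
effects because only reciprocally similar spot pairs qualify.  The
union of both edge kinds is the composed graph whose adjacency drives
the graph attention encoder.

Distance ties are broken by lower spot index so edge sets are
deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .datasets import MultiSliceDataset
from .preprocessing import SpotIndexMap

logger = logging.getLogger(__name__)

__all__ = ["ComposedGraph", "build_spatial_edges", "build_mnn_edges", "compose"]

DEFAULT_SPATIAL_K = 5
DEFAULT_MNN_K = 5
DEFAULT_PCA_DIM = 50


@dataclass
class ComposedGraph:
    """Typed edge set over the spots of a slice subset.

    ``edges`` holds undirected edges once, as ``(src, dst, kind)`` with
    ``src < dst`` and ``kind`` in ``{"spatial", "mnn"}``.  The adjacency
    is binary, symmetric, with a zero diagonal (self-loops are added
    only inside the attention layer).
    """

    n_nodes: int
    edges: list[tuple[int, int, str]]
    index_map: SpotIndexMap

    def __post_init__(self):
        self.edges = sorted({(min(s, d), max(s, d), k) for s, d, k in self.edges})

    @property
    def adjacency(self) -> sp.csr_matrix:
        if not self.edges:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        src, dst, _ = zip(*self.edges)
        row = np.concatenate([src, dst])
        col = np.concatenate([dst, src])
        a = sp.csr_matrix(
            (np.ones(row.size), (row, col)), shape=(self.n_nodes, self.n_nodes)
        )
        a.data[:] = 1.0  # collapse duplicate spatial/mnn pairs
        return a

    def edge_kinds(self) -> dict[str, int]:
        counts = {"spatial": 0, "mnn": 0}
        for _, _, k in self.edges:
            counts[k] += 1
        return counts

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("src\tdst\tkind\n")
            for s, d, k in self.edges:
                fh.write(f"{s}\t{d}\t{k}\n")

    def to_mtx(self, path) -> None:
        """Export the binary adjacency in Matrix Market format."""
        from scipy.io import mmwrite

        mmwrite(str(path), self.adjacency)

    @classmethod
    def from_tsv(cls, path, n_nodes: int, index_map: SpotIndexMap) -> "ComposedGraph":
        edges = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                s, d, k = line.rstrip("\n").split("\t")
                edges.append((int(s), int(d), k))
        return cls(n_nodes=n_nodes, edges=edges, index_map=index_map)


def _knn_indices(query: np.ndarray, pool: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest pool rows per query row.

    Ties broken by lower pool index (stable lexicographic argsort).
    """
    d = cdist(query, pool)
    n_pool = pool.shape[0]
    idx = np.arange(n_pool)
    order = np.empty((query.shape[0], k), dtype=np.intp)
    for i in range(query.shape[0]):
        order[i] = idx[np.lexsort((idx, d[i]))][:k]
    return order


def build_spatial_edges(coords: np.ndarray, avg_k: int = DEFAULT_SPATIAL_K):
    """Symmetrized spatial k-NN edges within one slice.

    Each spot is linked to its ``avg_k`` nearest neighbors; the union of
    directed links makes ``avg_k`` the minimum (approximately average)
    degree.  Slices with fewer than ``avg_k + 1`` spots fall back to a
    complete graph with a warning.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("spatial graph needs at least 2 spots")
    if avg_k < 1:
        raise ValueError("avg_k must be >= 1")
    k = avg_k
    if n <= avg_k:
        warnings.warn(
            f"slice has {n} spots <= avg_k={avg_k}; connecting to all others",
            stacklevel=2,
        )
        k = n - 1
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    idx = np.arange(n)
    edges = set()
    for i in range(n):
        for j in idx[np.lexsort((idx, d[i]))][:k]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return sorted(edges)


def build_mnn_edges(feat_a: np.ndarray, feat_b: np.ndarray, k: int = DEFAULT_MNN_K):
    """Mutual nearest neighbor pairs between two feature matrices.

    ``(a, b)`` is an edge iff ``b`` is among the ``k`` nearest rows of
    ``feat_b`` to ``a`` AND ``a`` is among the ``k`` nearest rows of
    ``feat_a`` to ``b`` (Euclidean distance).
    """
    feat_a = np.atleast_2d(np.asarray(feat_a, dtype=np.float64))
    feat_b = np.atleast_2d(np.asarray(feat_b, dtype=np.float64))
    if feat_a.size == 0 or feat_b.size == 0:
        warnings.warn("empty feature matrix: no MNN edges", stacklevel=2)
        return []
    if feat_a.shape[1] != feat_b.shape[1]:
        raise ValueError("feature dimension mismatch")
    ka = min(k, feat_b.shape[0])
    kb = min(k, feat_a.shape[0])
    nn_ab = _knn_indices(feat_a, feat_b, ka)  # per a-row: b candidates
    nn_ba = _knn_indices(feat_b, feat_a, kb)  # per b-row: a candidates
    b_of = [set(row.tolist()) for row in nn_ab]
    edges = []
    for b, a_candidates in enumerate(nn_ba):
        for a in a_candidates:
            if b in b_of[a]:
                edges.append((int(a), int(b)))
    return sorted(edges)


def _mnn_features(X: np.ndarray, pca_dim: int) -> np.ndarray:
    """Shared feature space for MNN search.

    Per-gene standardization (clipped at 10 standard deviations, the
    standard single-cell workflow) followed by the top principal
    components; raw HVG space makes k-NN noisy.
    """
    n, m = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = np.clip((X - mu) / sd, -10, 10)
    dim = min(pca_dim, n - 1, m)
    if dim < 1:
        return Xs
    from sklearn.decomposition import PCA

    return PCA(n_components=dim, svd_solver="full").fit_transform(Xs)


def compose(
    dataset: MultiSliceDataset,
    X: np.ndarray,
    index_map: SpotIndexMap,
    avg_k: int = DEFAULT_SPATIAL_K,
    mnn_k: int = DEFAULT_MNN_K,
    pca_dim: int = DEFAULT_PCA_DIM,
) -> ComposedGraph:
    """Build the composed graph for the slice subset behind ``index_map``.

    Spatial k-NN edges are computed per slice on coordinates; MNN edges
    on the top principal components of ``X`` for every unordered pair of
    included slices.
    """
    if X.shape[0] != index_map.n_rows:
        raise ValueError("X rows do not match index map")
    by_id = {s.slice_id: s for s in dataset.slices}
    edges: list[tuple[int, int, str]] = []
    for sid in index_map.slice_ids:
        rows = index_map.rows_of(sid)
        for i, j in build_spatial_edges(by_id[sid].coords, avg_k=avg_k):
            edges.append((int(rows[i]), int(rows[j]), "spatial"))
    feats = _mnn_features(X, pca_dim)
    ids = list(index_map.slice_ids)
    for ia in range(len(ids)):
        rows_a = index_map.rows_of(ids[ia])
        for ib in range(ia + 1, len(ids)):
            rows_b = index_map.rows_of(ids[ib])
            for a, b in build_mnn_edges(feats[rows_a], feats[rows_b], k=mnn_k):
                edges.append((int(rows_a[a]), int(rows_b[b]), "mnn"))
    graph = ComposedGraph(n_nodes=index_map.n_rows, edges=edges, index_map=index_map)
    kinds = graph.edge_kinds()
    logger.info(
        "composed graph: %d nodes, %d spatial + %d mnn edges",
        graph.n_nodes,
        kinds["spatial"],
        kinds["mnn"],
    )
    return graph
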