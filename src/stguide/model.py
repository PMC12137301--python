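"""The stGuide model: two-phase supervised graph representation learning.

Phase 1 trains a graph attention autoencoder on the reference slices
alone, with a classifier head supervised by the reference annotations;
its latent embedding ``z_r`` is category-informed and batch-mixed.
Phase 2 trains a fresh autoencoder jointly on reference and query
slices, with an alignment penalty pulling the reference rows of the
joint embedding ``z_r'`` toward the frozen ``z_r``; query spots thereby
land in the supervised space and labels can be transferred by cosine
similarity.

The interface follows the Model/Results convention: build
:class:`StGuide` from a :class:`~stguide.datasets.MultiSliceDataset`,
call :meth:`StGuide.fit`, and read estimates off the returned
:class:`StGuideResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._autograd import Tensor
from .datasets import MultiSliceDataset
from .graph import (
    DEFAULT_MNN_K,
    DEFAULT_PCA_DIM,
    DEFAULT_SPATIAL_K,
    ComposedGraph,
    compose,
)
from .losses import (
    DENSE_ADJ_LIMIT,
    LossWeights,
    adjacency_loss,
    classification_loss,
    expression_loss,
    phase1_total,
    phase2_total,
    transfer_loss,
)
from .network import StGuideNetwork, attention_mask, decode_adjacency
from .preprocessing import DEFAULT_N_TOP_HVGS, preprocess_dataset
from .transfer import TransferResult, transfer_labels

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "StGuide", "StGuideResults", "train_phase1", "train_phase2"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by both phases."""

    epochs_phase1: int = 800
    epochs_phase2: int = 800
    learning_rate: float = 2e-3
    weight_decay: float = 1e-4
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    warm_start_phase2: bool = False

    def __post_init__(self):
        if self.epochs_phase1 < 1 or self.epochs_phase2 < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _expression_loss_blocks(z, net, X, index_map, mode):
    """Mean per-spot squared reconstruction error, decoded slice by slice."""
    n = X.shape[0]
    sse = None
    for sid in index_map.slice_ids:
        rows = index_map.rows_of(sid)
        x_rec = net.decoders[sid].forward(z.take_rows(rows), mode=mode)
        block = ((x_rec - Tensor(X[rows])) ** 2.0).sum()
        sse = block if sse is None else sse + block
    return sse * (1.0 / n)


def _adjacency_term(z, A_dense, A_sparse, rng):
    n = A_sparse.shape[0]
    if n <= DENSE_ADJ_LIMIT:
        return adjacency_loss(decode_adjacency(z), A_dense)

    def entries(rows, cols):
        return (z.take_rows(rows) * z.take_rows(cols)).sum(axis=1).sigmoid()

    return adjacency_loss(entries, A_sparse, rng=rng)


def _check_finite(total, epoch, components):
    if not np.isfinite(total.data):
        detail = ", ".join(f"{k}={v:.4g}" for k, v in components.items())
        raise FloatingPointError(
            f"non-finite training loss at epoch {epoch} ({detail})"
        )


def train_phase1(
    X_ref: np.ndarray,
    graph: ComposedGraph,
    y_codes: np.ndarray,
    n_classes: int,
    config: TrainConfig,
    hidden_dim: int = 512,
    latent_dim: int = 10,
    n_heads: int = 3,
):
    """Supervised reference training; returns (z_r, network, loss trace)."""
    if np.unique(y_codes).size != n_classes:
        missing = sorted(set(range(n_classes)) - set(np.unique(y_codes)))
        raise ValueError(f"classes absent from the reference: {missing}")
    net = StGuideNetwork(
        n_genes=X_ref.shape[1],
        slice_ids=list(graph.index_map.slice_ids),
        n_classes=n_classes,
        hidden_dim=hidden_dim,
        latent_dim=latent_dim,
        n_heads=n_heads,
        seed=config.seed,
    )
    opt = net.make_optimizer(config.learning_rate, config.weight_decay)
    mask = attention_mask(graph.adjacency)
    A_sparse = graph.adjacency
    A_dense = np.asarray(A_sparse.todense())
    rng = np.random.default_rng(config.seed)
    xt = Tensor(X_ref)
    trace = []
    for epoch in range(config.epochs_phase1):
        opt.zero_grad()
        z = net.encoder.forward(xt, mask)
        l_adj = _adjacency_term(z, A_dense, A_sparse, rng)
        l_expr = _expression_loss_blocks(z, net, X_ref, graph.index_map, "train")
        l_cls = classification_loss(net.classifier.forward(z), y_codes)
        total = phase1_total(l_adj, l_expr, l_cls, config.weights)
        comps = {
            "L_A": float(l_adj.data),
            "L_G": float(l_expr.data),
            "L_c": float(l_cls.data),
            "total": float(total.data),
        }
        _check_finite(total, epoch, comps)
        trace.append({"epoch": epoch, **comps})
        total.backward()
        opt.step()
    z_r = net.encoder.forward(xt, mask).data
    return z_r, net, pd.DataFrame(trace)


def train_phase2(
    X_all: np.ndarray,
    graph: ComposedGraph,
    z_r: np.ndarray,
    n_ref_spots: int,
    config: TrainConfig,
    hidden_dim: int = 512,
    latent_dim: int = 10,
    n_heads: int = 3,
    warm_start_from: StGuideNetwork | None = None,
):
    """Joint reference+query training aligned to the frozen ``z_r``.

    Returns (z_r_prime, z_q, network, loss trace).
    """
    if z_r.shape[0] != n_ref_spots:
        raise ValueError("z_r rows do not match the reference spot count")
    ref_rows = np.arange(n_ref_spots)
    net = StGuideNetwork(
        n_genes=X_all.shape[1],
        slice_ids=list(graph.index_map.slice_ids),
        n_classes=None,
        hidden_dim=hidden_dim,
        latent_dim=latent_dim,
        n_heads=n_heads,
        seed=config.seed + 1,
    )
    if warm_start_from is not None:
        for dst, src in zip(net.encoder.layers, warm_start_from.encoder.layers):
            for q in range(dst.n_heads):
                dst.W[q].data = src.W[q].data.copy()
                dst.a_src[q].data = src.a_src[q].data.copy()
                dst.a_dst[q].data = src.a_dst[q].data.copy()
    opt = net.make_optimizer(config.learning_rate, config.weight_decay)
    mask = attention_mask(graph.adjacency)
    A_sparse = graph.adjacency
    A_dense = np.asarray(A_sparse.todense())
    rng = np.random.default_rng(config.seed + 1)
    xt = Tensor(X_all)
    trace = []
    for epoch in range(config.epochs_phase2):
        opt.zero_grad()
        z = net.encoder.forward(xt, mask)
        l_adj = _adjacency_term(z, A_dense, A_sparse, rng)
        l_expr = _expression_loss_blocks(z, net, X_all, graph.index_map, "train")
        l_tl = transfer_loss(z_r, z.take_rows(ref_rows))
        total = phase2_total(l_adj, l_expr, l_tl, config.weights)
        comps = {
            "L_A": float(l_adj.data),
            "L_G": float(l_expr.data),
            "L_TL": float(l_tl.data),
            "total": float(total.data),
        }
        _check_finite(total, epoch, comps)
        trace.append({"epoch": epoch, **comps})
        total.backward()
        opt.step()
    z_all = net.encoder.forward(xt, mask).data
    return z_all[:n_ref_spots], z_all[n_ref_spots:], net, pd.DataFrame(trace)


class StGuide:
    """Attention-based supervised graph representation model.

    Construction preprocesses the dataset (normalization, HVG
    intersection, concatenation) and builds the two composed graphs; the
    heavy optimization happens in :meth:`fit`.

    Parameters
    ----------
    dataset : MultiSliceDataset
        Reference slices (annotated) followed by query slices.
    n_top_hvgs : int
        Highly variable genes selected per slice before intersection.
    avg_k, mnn_k : int
        Spatial k-NN and cross-slice mutual-NN neighborhood sizes.
    pca_dim : int
        Principal components used as the MNN feature space.
    hidden_dim, latent_dim, n_heads : int
        Encoder architecture (two GAT layers, mean-aggregated heads).
    """

    def __init__(
        self,
        dataset: MultiSliceDataset,
        n_top_hvgs: int = DEFAULT_N_TOP_HVGS,
        avg_k: int = DEFAULT_SPATIAL_K,
        mnn_k: int = DEFAULT_MNN_K,
        pca_dim: int = DEFAULT_PCA_DIM,
        hidden_dim: int = 512,
        latent_dim: int = 10,
        n_heads: int = 3,
    ):
        self.dataset = dataset
        self.hidden_dim = hidden_dim
        self.latent_dim = latent_dim
        self.n_heads = n_heads
        (
            self.genes,
            self.X_ref,
            self.map_ref,
            self.X_all,
            self.map_all,
        ) = preprocess_dataset(dataset, n_top=n_top_hvgs)
        self.graph_ref = compose(
            dataset, self.X_ref, self.map_ref, avg_k=avg_k, mnn_k=mnn_k, pca_dim=pca_dim
        )
        self.graph_all = compose(
            dataset, self.X_all, self.map_all, avg_k=avg_k, mnn_k=mnn_k, pca_dim=pca_dim
        )
        self.label_categories = dataset.label_categories
        self.y_ref = np.concatenate(
            [dataset.label_codes(s) for s in dataset.reference_slices]
        )

    @classmethod
    def from_slices(cls, slices, hidden_labels=None, **kwargs) -> "StGuide":
        ds = MultiSliceDataset(list(slices), hidden_labels=dict(hidden_labels or {}))
        return cls(ds, **kwargs)

    def fit(self, config: TrainConfig | None = None, **overrides) -> "StGuideResults":
        """Run both training phases and return the fitted results."""
        config = replace(config or TrainConfig(), **overrides)
        logger.info("phase 1: %d reference spots", self.X_ref.shape[0])
        z_r, net1, trace1 = train_phase1(
            self.X_ref,
            self.graph_ref,
            self.y_ref,
            len(self.label_categories),
            config,
            self.hidden_dim,
            self.latent_dim,
            self.n_heads,
        )
        logger.info("phase 2: %d total spots", self.X_all.shape[0])
        z_rp, z_q, net2, trace2 = train_phase2(
            self.X_all,
            self.graph_all,
            z_r,
            self.X_ref.shape[0],
            config,
            self.hidden_dim,
            self.latent_dim,
            self.n_heads,
            warm_start_from=net1 if config.warm_start_phase2 else None,
        )
        return StGuideResults(
            model=self,
            config=config,
            z_r=z_r,
            z_r_prime=z_rp,
            z_q=z_q,
            trace_phase1=trace1,
            trace_phase2=trace2,
            network_phase1=net1,
            network_phase2=net2,
        )


@dataclass
class StGuideResults:
    """Fitted embeddings, diagnostics, and downstream label transfer."""

    model: StGuide
    config: TrainConfig
    z_r: np.ndarray
    z_r_prime: np.ndarray
    z_q: np.ndarray
    trace_phase1: pd.DataFrame
    trace_phase2: pd.DataFrame
    network_phase1: StGuideNetwork
    network_phase2: StGuideNetwork

    def transfer(self, k: int = 1) -> TransferResult:
        """Assign reference labels to query spots by cosine similarity."""
        return transfer_labels(self.z_q, self.z_r_prime, self.model.y_ref, k=k)

    def predictions_frame(self, k: int = 1) -> pd.DataFrame:
        """Per-query-spot predictions as a tidy table."""
        result = self.transfer(k=k)
        cats = self.model.label_categories
        rows = []
        query_map = self.model.map_all
        n_ref = self.z_r.shape[0]
        for g, (code, sim) in enumerate(
            zip(result.predicted_label, result.best_similarity)
        ):
            sid, local = query_map.locate(n_ref + g)
            rows.append(
                {
                    "slice_id": sid,
                    "spot_id": local,
                    "predicted_label": cats[code],
                    "best_similarity": sim,
                }
            )
        return pd.DataFrame(rows)

    def evaluate(self, k: int = 1):
        """Metrics against the dataset's hidden query annotations."""
        from .evaluation import compute_metrics

        ds = self.model.dataset
        truth = []
        for s in ds.query_slices:
            if s.slice_id not in ds.hidden_labels:
                raise ValueError(f"no hidden labels for query slice {s.slice_id!r}")
            truth.append(ds.hidden_labels[s.slice_id])
        y_true = np.concatenate(truth)
        cats = self.model.label_categories
        lut = {c: i for i, c in enumerate(cats)}
        y_true_codes = np.array([lut.get(str(v), -1) for v in y_true], dtype=np.intp)
        y_pred_codes = self.transfer(k=k).predicted_label
        return compute_metrics(y_true_codes, y_pred_codes)

    def alignment_mean_cosine(self) -> float:
        """Mean row-wise cosine between z_r and z_r' (alignment quality)."""
        a, b = self.z_r, self.z_r_prime
        num = (a * b).sum(axis=1)
        den = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        den[den == 0] = 1.0
        return float(np.mean(num / den))

    def alignment_mean_sq_distance(self) -> float:
        return float(np.mean(((self.z_r - self.z_r_prime) ** 2).sum(axis=1)))

    def pseudotime(self, root: int, use: str = "all") -> np.ndarray:
        """Diffusion pseudotime on the learned embedding (external DPT)."""
        from .transfer import pseudotime_hook

        emb = {
            "all": np.vstack([self.z_r_prime, self.z_q]),
            "reference": self.z_r_prime,
            "query": self.z_q,
        }[use]
        return pseudotime_hook(emb, root)

    def summary(self) -> str:
        """Human-readable fit report."""
        ds = self.model.dataset
        lines = [
            "stGuide fit summary",
            "===================",
            f"slices: {ds.K} reference + {ds.L} query",
            f"common genes: {len(self.model.genes)}",
            f"latent dimension: {self.z_r.shape[1]}",
            f"label categories ({len(self.model.label_categories)}): "
            + ", ".join(self.model.label_categories),
            "",
            "phase 1 (supervised reference training)",
            f"  epochs: {len(self.trace_phase1)}",
            f"  total loss: {self.trace_phase1['total'].iloc[0]:.4f} -> "
            f"{self.trace_phase1['total'].iloc[-1]:.4f}",
            "phase 2 (knowledge-guided joint training)",
            f"  epochs: {len(self.trace_phase2)}",
            f"  total loss: {self.trace_phase2['total'].iloc[0]:.4f} -> "
            f"{self.trace_phase2['total'].iloc[-1]:.4f}",
            f"  alignment mean cosine(z_r, z_r'): {self.alignment_mean_cosine():.4f}",
        ]
        return "\n".join(lines)
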