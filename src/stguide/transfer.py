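"""Label transfer from reference to query spots in the shared embedding.

Each query spot is compared against every reference spot by cosine
similarity.  With ``k=1`` (the default) the label of the single most
similar reference spot is assigned; with ``k>1`` the top-``k`` reference
neighbors vote by majority, ties broken by higher summed similarity and
then by lower label code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["TransferResult", "transfer_labels", "pseudotime_hook"]


@dataclass
class TransferResult:
    """Per-query-spot label assignment with similarity diagnostics."""

    predicted_label: np.ndarray  # integer category codes
    best_similarity: np.ndarray  # in [-1, 1]
    neighbor_ids: np.ndarray  # (n_query, k_used) reference row indices
    k_used: int


def _row_normalize(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if np.any(zero):
        logger.warning(
            "%d zero-norm embedding rows treated as similarity 0", int(zero.sum())
        )
    safe = np.where(zero, 1.0, norms)
    return x / safe[:, None]


def transfer_labels(
    z_query: np.ndarray,
    z_reference: np.ndarray,
    y_reference: np.ndarray,
    k: int = 1,
) -> TransferResult:
    """Assign reference labels to query spots by cosine similarity.

    Parameters
    ----------
    z_query, z_reference : ndarray
        Row-aligned embeddings with a common column dimension.
    y_reference : ndarray of int
        Reference label codes, aligned with ``z_reference`` rows.
    k : int
        Number of reference neighbors; ``k=1`` assigns the argmax.
    """
    z_query = np.atleast_2d(np.asarray(z_query, dtype=np.float64))
    z_reference = np.atleast_2d(np.asarray(z_reference, dtype=np.float64))
    y_reference = np.asarray(y_reference, dtype=np.intp)
    if z_query.shape[1] != z_reference.shape[1]:
        raise ValueError("embedding dimensions differ")
    if y_reference.shape[0] != z_reference.shape[0]:
        raise ValueError("reference labels misaligned")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, z_reference.shape[0])
    sims = _row_normalize(z_query) @ _row_normalize(z_reference).T
    n_query, n_ref = sims.shape
    ref_idx = np.arange(n_ref)
    predicted = np.empty(n_query, dtype=np.intp)
    best = np.empty(n_query)
    neighbors = np.empty((n_query, k), dtype=np.intp)
    for i in range(n_query):
        order = ref_idx[np.lexsort((ref_idx, -sims[i]))][:k]
        neighbors[i] = order
        best[i] = sims[i, order[0]]
        if k == 1:
            predicted[i] = y_reference[order[0]]
            continue
        labels = y_reference[order]
        codes = np.unique(labels)
        votes = np.array([(labels == c).sum() for c in codes])
        sim_sums = np.array([sims[i, order[labels == c]].sum() for c in codes])
        # majority; ties -> higher summed similarity -> lower label code
        pick = codes[np.lexsort((codes, -sim_sums, -votes))][0]
        predicted[i] = pick
    return TransferResult(
        predicted_label=predicted,
        best_similarity=best,
        neighbor_ids=neighbors,
        k_used=k,
    )


def pseudotime_hook(embedding: np.ndarray, root: int) -> np.ndarray:
    """Diffusion pseudotime on an embedding, delegated to scanpy's DPT.

    The pseudotime algorithm itself is external prior work; this hook
    only wires the learned embedding into it and returns its output
    untouched (pseudotime 0 at the root spot).
    """
    try:
        import anndata as ad
        import scanpy as sc
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "pseudotime requires the 'scanpy' and 'anndata' packages"
        ) from exc
    embedding = np.atleast_2d(np.asarray(embedding, dtype=np.float64))
    if embedding.shape[0] == 0:
        raise ValueError("empty embedding")
    if not 0 <= root < embedding.shape[0]:
        raise IndexError(f"root {root} out of range")
    if np.allclose(embedding, embedding[0]):
        warnings.warn("constant embedding: pseudotime is degenerate", stacklevel=2)
    adata = ad.AnnData(X=embedding.copy())
    adata.obsm["X_emb"] = embedding.copy()
    n_neighbors = min(15, embedding.shape[0] - 1)
    sc.pp.neighbors(adata, use_rep="X_emb", n_neighbors=n_neighbors)
    adata.uns["iroot"] = int(root)
    sc.tl.diffmap(adata)
    sc.tl.dpt(adata)
    return adata.obs["dpt_pseudotime"].to_numpy()
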