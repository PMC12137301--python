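"""Expression preprocessing: normalization, HVG intersection, assembly.

Raw per-slice count matrices are library-size normalized to a fixed
total per spot, log1p-transformed, restricted to the intersection of
per-slice highly variable genes, and concatenated row-wise into the
model input ``X``.  The module is deterministic: reprocessing the same
dataset yields bitwise-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .datasets import MultiSliceDataset, SliceData

__all__ = [
    "normalize_log",
    "select_common_hvgs",
    "assemble_input",
    "preprocess_dataset",
    "SpotIndexMap",
]

TARGET_TOTAL = 1e4  # counts per spot after library-size normalization
DEFAULT_N_TOP_HVGS = 5000


def normalize_log(expression: np.ndarray, target_total: float = TARGET_TOTAL) -> np.ndarray:
    """Scale each spot to ``target_total`` counts, then ``log(1+x)``.

    Raises
    ------
    ValueError
        If any entry is negative or any spot has zero total counts.
    """
    x = np.asarray(expression, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("expression contains negative entries")
    totals = x.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"spot rows with zero total counts cannot be normalized: "
            f"indices {zero[:10].tolist()}"
        )
    return np.log1p(x * (target_total / totals)[:, None])


def _hvg_ranking(slice_data: SliceData, target_total: float) -> list[str]:
    """Genes ranked by mean-binned normalized dispersion on log data.

    Ties are broken lexicographically by gene name so the ranking is
    deterministic.
    """
    import scanpy as sc

    from .datasets import slice_to_anndata

    adata = slice_to_anndata(slice_data)
    adata.X = normalize_log(slice_data.expression, target_total)
    sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=adata.n_vars)
    disp = adata.var["dispersions_norm"].to_numpy(dtype=np.float64)
    disp = np.nan_to_num(disp, nan=-np.inf)
    names = np.asarray(adata.var_names)
    order = np.lexsort((names, -disp))
    return [str(n) for n in names[order]]


def select_common_hvgs(
    dataset: MultiSliceDataset,
    n_top: int = DEFAULT_N_TOP_HVGS,
    target_total: float = TARGET_TOTAL,
) -> list[str]:
    """Intersect each slice's top-``n_top`` highly variable genes.

    ``n_top`` is clipped to each slice's gene count.  The result is
    sorted lexicographically.

    Raises
    ------
    ValueError
        If the intersection is empty.
    """
    common: set[str] | None = None
    for s in dataset.slices:
        top = set(_hvg_ranking(s, target_total)[: min(n_top, len(s.gene_names))])
        common = top if common is None else (common & top)
    if not common:
        raise ValueError(
            "HVG intersection across slices is empty; decrease n_top or use "
            "slices sharing a gene panel"
        )
    return sorted(common)


@dataclass(frozen=True)
class SpotIndexMap:
    """Maps global row -> (slice_id, local row) for an assembled matrix."""

    slice_ids: tuple[str, ...]
    sizes: tuple[int, ...]

    @property
    def n_rows(self) -> int:
        return sum(self.sizes)

    def locate(self, global_row: int) -> tuple[str, int]:
        offset = 0
        for sid, n in zip(self.slice_ids, self.sizes):
            if global_row < offset + n:
                return sid, global_row - offset
            offset += n
        raise IndexError(global_row)

    def rows_of(self, slice_id: str) -> np.ndarray:
        offset = 0
        for sid, n in zip(self.slice_ids, self.sizes):
            if sid == slice_id:
                return np.arange(offset, offset + n)
            offset += n
        raise KeyError(slice_id)


def assemble_input(
    dataset: MultiSliceDataset,
    genes: list[str],
    subset: str = "all",
    target_total: float = TARGET_TOTAL,
) -> tuple[np.ndarray, SpotIndexMap]:
    """Concatenate normalized slices row-wise on a common gene set.

    Rows follow slice order (reference first) then within-slice spot
    order; columns follow ``genes``.

    Parameters
    ----------
    subset : {"all", "reference_only"}
    """
    if subset not in ("all", "reference_only"):
        raise ValueError(f"unknown subset {subset!r}")
    slices = dataset.reference_slices if subset == "reference_only" else dataset.slices
    blocks = []
    for s in slices:
        col = {g: i for i, g in enumerate(s.gene_names)}
        missing = [g for g in genes if g not in col]
        if missing:
            raise ValueError(
                f"slice {s.slice_id!r} lacks genes {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        idx = np.array([col[g] for g in genes], dtype=np.intp)
        blocks.append(normalize_log(s.expression, target_total)[:, idx])
    index_map = SpotIndexMap(
        slice_ids=tuple(s.slice_id for s in slices),
        sizes=tuple(s.n_spots for s in slices),
    )
    return np.vstack(blocks), index_map


def gene_list_hash(genes: list[str]) -> str:
    return hashlib.sha256("\n".join(genes).encode()).hexdigest()[:16]


def write_processed_h5ad(
    dataset: MultiSliceDataset,
    genes: list[str],
    path,
    n_top: int = DEFAULT_N_TOP_HVGS,
    target_total: float = TARGET_TOTAL,
) -> None:
    """Write the assembled, normalized dataset with provenance metadata."""
    import anndata as ad
    import pandas as pd

    X, index_map = assemble_input(dataset, genes, "all", target_total)
    obs_slice = []
    obs_label = []
    for s in dataset.slices:
        obs_slice += [s.slice_id] * s.n_spots
        labels = (
            s.labels
            if s.labels is not None
            else dataset.hidden_labels.get(s.slice_id, np.full(s.n_spots, ""))
        )
        obs_label += [str(v) for v in labels]
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(
            {"slice_id": obs_slice, "label": obs_label},
            index=[f"spot_{i}" for i in range(X.shape[0])],
        ),
        var=pd.DataFrame(index=list(genes)),
    )
    adata.obsm["spatial"] = np.vstack([s.coords for s in dataset.slices])
    adata.uns["stguide"] = {
        "n_top_hvgs": int(n_top),
        "target_total": float(target_total),
        "gene_list_hash": gene_list_hash(genes),
    }
    adata.write_h5ad(path)


def preprocess_dataset(
    dataset: MultiSliceDataset,
    n_top: int = DEFAULT_N_TOP_HVGS,
    target_total: float = TARGET_TOTAL,
):
    """Full preprocessing: HVG intersection plus both assembled inputs.

    Returns
    -------
    genes : list of str
    X_ref, map_ref : reference-only input and its index map
    X_all, map_all : reference+query input and its index map
    """
    genes = select_common_hvgs(dataset, n_top=n_top, target_total=target_total)
    X_ref, map_ref = assemble_input(dataset, genes, "reference_only", target_total)
    X_all, map_all = assemble_input(dataset, genes, "all", target_total)
    return genes, X_ref, map_ref, X_all, map_all
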