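"""Containers for multi-slice spatial transcriptomics data.

A *slice* is one tissue section: a spots x genes count matrix, 2-D spot
coordinates, and — for reference slices — a categorical annotation per
spot.  A :class:`MultiSliceDataset` holds the K reference slices followed
by the L query slices; the user-supplied order defines the slice indices
used everywhere downstream (decoders, index maps, concatenation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SliceData", "MultiSliceDataset", "read_slice_h5ad", "read_slice_csv"]


@dataclass
class SliceData:
    """One spatial transcriptomics section.

    Parameters
    ----------
    slice_id : str
        Unique name of the section.
    expression : ndarray, shape (n_spots, n_genes)
        Non-negative expression values (raw counts unless noted).
    coords : ndarray, shape (n_spots, 2)
        Spatial coordinates in platform units.
    gene_names : sequence of str
        Column names of ``expression``; must be unique.
    labels : ndarray of str or None
        Per-spot annotation. Required for reference slices, forbidden
        for query slices (hidden truth is carried separately).
    role : {"reference", "query"}
    """

    slice_id: str
    expression: np.ndarray
    coords: np.ndarray
    gene_names: list[str]
    labels: np.ndarray | None = None
    role: str = "reference"

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.gene_names = list(map(str, self.gene_names))
        if self.role not in ("reference", "query"):
            raise ValueError(f"role must be 'reference' or 'query', got {self.role!r}")
        if self.coords.shape != (self.expression.shape[0], 2):
            raise ValueError(
                f"slice {self.slice_id!r}: coords shape {self.coords.shape} does not "
                f"match {self.expression.shape[0]} spots x 2"
            )
        if len(self.gene_names) != self.expression.shape[1]:
            raise ValueError(f"slice {self.slice_id!r}: gene name count mismatch")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError(f"slice {self.slice_id!r}: duplicated gene names")
        if self.role == "reference" and self.labels is None:
            raise ValueError(f"reference slice {self.slice_id!r} lacks labels")
        if self.role == "query" and self.labels is not None:
            raise ValueError(f"query slice {self.slice_id!r} must not carry labels")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.expression.shape[0]:
                raise ValueError(f"slice {self.slice_id!r}: label length mismatch")

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]


@dataclass
class MultiSliceDataset:
    """Ordered collection of reference then query slices.

    ``label_categories`` is the shared annotation vocabulary (ordered);
    integer label codes index into it.  ``hidden_labels`` optionally maps
    a query ``slice_id`` to its ground-truth annotation, used only for
    evaluation on simulated or benchmark data.
    """

    slices: list[SliceData]
    hidden_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        roles = [s.role for s in self.slices]
        if "reference" not in roles:
            raise ValueError("at least one reference slice is required")
        k = roles.count("reference")
        if any(r == "reference" for r in roles[k:]):
            raise ValueError("reference slices must precede query slices")
        ids = [s.slice_id for s in self.slices]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated slice_id")

    @property
    def K(self) -> int:
        return sum(s.role == "reference" for s in self.slices)

    @property
    def L(self) -> int:
        return len(self.slices) - self.K

    @property
    def reference_slices(self) -> list[SliceData]:
        return self.slices[: self.K]

    @property
    def query_slices(self) -> list[SliceData]:
        return self.slices[self.K :]

    @property
    def label_categories(self) -> list[str]:
        cats: set[str] = set()
        for s in self.reference_slices:
            cats.update(map(str, s.labels))
        return sorted(cats)

    def label_codes(self, slice_data: SliceData) -> np.ndarray:
        """Integer codes of a labeled slice in the shared vocabulary."""
        lut = {c: i for i, c in enumerate(self.label_categories)}
        return np.array([lut[str(v)] for v in slice_data.labels], dtype=np.intp)


def read_slice_h5ad(
    path,
    slice_id: str | None = None,
    role: str = "reference",
    label_key: str = "label",
    layer: str | None = None,
) -> SliceData:
    """Load one slice from an AnnData ``.h5ad`` file.

    Expression is taken from ``adata.X`` (or the named layer), coordinates
    from ``obsm["spatial"]``, labels from the ``label_key`` obs column.
    """
    import anndata as ad
    import scipy.sparse as sp

    adata = ad.read_h5ad(path)
    x = adata.layers[layer] if layer is not None else adata.X
    if sp.issparse(x):
        x = x.toarray()
    if "spatial" not in adata.obsm:
        raise KeyError(f"{path}: obsm['spatial'] not found")
    labels = None
    if role == "reference":
        if label_key not in adata.obs:
            raise KeyError(f"{path}: obs[{label_key!r}] not found")
        labels = adata.obs[label_key].astype(str).to_numpy()
    return SliceData(
        slice_id=slice_id or str(path),
        expression=np.asarray(x, dtype=np.float64),
        coords=np.asarray(adata.obsm["spatial"], dtype=np.float64)[:, :2],
        gene_names=list(adata.var_names),
        labels=labels,
        role=role,
    )


def slice_to_anndata(slice_data: SliceData):
    """Convert a slice to AnnData (coordinates in obsm['spatial'])."""
    import anndata as ad

    adata = ad.AnnData(
        X=slice_data.expression.copy(),
        obs=pd.DataFrame(index=[f"spot_{i}" for i in range(slice_data.n_spots)]),
        var=pd.DataFrame(index=list(slice_data.gene_names)),
    )
    adata.obsm["spatial"] = slice_data.coords.copy()
    if slice_data.labels is not None:
        adata.obs["label"] = pd.Categorical(slice_data.labels.astype(str))
    return adata


def read_slice_csv(
    matrix_path, spots_path, slice_id: str, role: str = "reference"
) -> SliceData:
    """Load one slice from a genes x spots matrix CSV and a spot table.

    The spot table has columns ``spot,x,y`` plus optional ``label``.
    """
    mat = pd.read_csv(matrix_path, index_col=0)
    spots = pd.read_csv(spots_path)
    for col in ("spot", "x", "y"):
        if col not in spots.columns:
            raise KeyError(f"{spots_path}: column {col!r} missing")
    spots = spots.set_index("spot").loc[mat.columns]
    labels = None
    if role == "reference":
        if "label" not in spots.columns:
            raise KeyError(f"{spots_path}: reference slice needs a 'label' column")
        labels = spots["label"].astype(str).to_numpy()
    return SliceData(
        slice_id=slice_id,
        expression=mat.to_numpy(dtype=np.float64).T,
        coords=spots[["x", "y"]].to_numpy(dtype=np.float64),
        gene_names=list(mat.index),
        labels=labels,
        role=role,
    )
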