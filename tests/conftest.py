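import numpy as np
import pytest

from stguide.datasets import MultiSliceDataset, SliceData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _grid_slice(slice_id, rng, n_spots=12, n_genes=8, role="reference", n_classes=2):
    rows = 3
    cols = n_spots // rows
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
    expr = rng.poisson(5.0, size=(n_spots, n_genes)).astype(float) + 1.0
    labels = None
    if role == "reference":
        labels = np.array([f"c{i % n_classes}" for i in range(n_spots)])
    return SliceData(
        slice_id=slice_id,
        expression=expr,
        coords=coords,
        gene_names=[f"g{j}" for j in range(n_genes)],
        labels=labels,
        role=role,
    )


@pytest.fixture
def small_dataset(rng):
    """1 reference + 1 query slice on a 3x4 grid, 8 genes."""
    ref = _grid_slice("ref", rng)
    query = _grid_slice("query", rng, role="query")
    return MultiSliceDataset([ref, query])


@pytest.fixture(scope="session")
def tiny_fixture():
    from stguide.simulate import make_toy_fixture

    return make_toy_fixture("tiny")
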