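import numpy as np
import pandas as pd
import pytest

import dstate as ds


@pytest.fixture(scope="session")
def toy_ref():
    """Small ground-truth reference shared across estimation/simulation tests."""
    spec = ds.ToyReferenceSpec(
        n_genes=150, n_cells_per_instance=100, n_samples=8, n_subpops=2, seed=42
    )
    return ds.make_toy_reference(spec)


@pytest.fixture(scope="session")
def sim_de(toy_ref):
    """Default-style simulation (10% DE) at reduced size."""
    _, params = toy_ref
    cfg = ds.SimConfig(n_subpops=2, n_genes=120, cells_per_instance=150, seed=7)
    return ds.simulate_dataset(params, cfg)


@pytest.fixture
def tiny_dataset():
    """Hand-built 3-gene x 4-cell reference with two samples in one cluster."""
    counts = ds.CountMatrix(
        np.array([[3, 1, 0, 2], [1, 0, 2, 2], [0, 1, 1, 0]]),
        ["g1", "g2", "g3"],
        ["c1", "c2", "c3", "c4"],
    )
    ann = pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2", "s2"],
            "cluster_id": ["k1", "k1", "k1", "k1"],
            "group_id": ["A", "A", "B", "B"],
        },
        index=counts.cell_ids,
    )
    return ds.ReferenceData(counts, ann)


def make_pseudobulk(matrix: pd.DataFrame, assay_type: str, design: ds.DesignSpec,
                    cluster: str = "k1") -> "ds.Pseudobulk":
    """Assemble a single-cluster Pseudobulk object directly for engine tests."""
    n_cells = pd.DataFrame(1, index=[cluster], columns=list(matrix.columns))
    lam = pd.DataFrame(
        [matrix.sum(axis=0).values], index=[cluster], columns=list(matrix.columns)
    )
    return ds.Pseudobulk({cluster: matrix}, assay_type, n_cells, lam, design)


@pytest.fixture
def two_group_design():
    return ds.DesignSpec(
        ["a1", "a2", "a3", "b1", "b2", "b3"],
        {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
        ("A", "B"),
    )
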