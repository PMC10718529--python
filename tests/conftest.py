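import numpy as np
import pandas as pd
import pytest

from mcfa import synthetic, views


@pytest.fixture(scope="session")
def small_multiview():
    """Two-view single-group dataset drawn from the generative model."""
    data, truth = synthetic.simulate_multiview(
        n_samples=30, view_features=(40, 50), K_true=2, noise_sd=0.3, seed=5
    )
    return data, truth


@pytest.fixture(scope="session")
def tiny_atlas():
    """Small synthetic single-cell atlas with planted structure."""
    cells, truth = synthetic.simulate_single_cell(
        n_samples_per_condition=6, n_cells=60, seed=17
    )
    return cells, truth


@pytest.fixture(scope="session")
def normalized_views(tiny_atlas):
    cells, _ = tiny_atlas
    pb = views.build_pseudobulk(cells, min_cells=25)
    return {ct: views.tmm_normalize(views.qc_filter_genes(v)) for ct, v in pb.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def simple_counts_view():
    """Hand-sized pseudobulk view for QC/TMM unit tests."""
    counts = pd.DataFrame(
        np.array([
            [120, 99, 0, 10, 500],
            [0, 50, 0, 20, 400],
            [0, 10, 0, 30, 300],
            [0, 0, 0, 40, 200],
        ]),
        index=[f"s{i}" for i in range(4)],
        columns=[f"g{i}" for i in range(5)],
    )
    return views.PseudobulkView(
        cell_type="ct",
        counts=counts,
        n_cells=pd.Series(50, index=counts.index),
        sample_meta=pd.DataFrame(index=counts.index),
    )
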