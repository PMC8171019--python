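import logging

import numpy as np
import pytest

from genesieve import ExpressionMatrix, generate_dataset
from genesieve.clustering import fit

logging.getLogger("genesieve").setLevel(logging.ERROR)


@pytest.fixture
def tiny_matrix():
    """3 cells x 4 genes with distinct values."""
    return ExpressionMatrix(
        values=np.array(
            [[1.0, 0.0, 2.0, 3.0], [0.0, 4.0, 5.0, 6.0], [7.0, 8.0, 0.0, 9.0]]
        ),
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["gA", "gB", "gC", "gD"],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The standard synthetic fixture: K=5, 500 cells, 50/2000 informative."""
    return generate_dataset(seed=0)


@pytest.fixture(scope="session")
def fitted_default(default_dataset):
    """Weight model fitted once on the standard fixture (shared, read-only)."""
    return fit(default_dataset.matrix, 5, c_delta=15.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
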