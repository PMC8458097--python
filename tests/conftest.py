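import numpy as np
import pandas as pd
import pytest

from cryptomics.core import CellAnnotation, CountMatrix, ExpressionMatrix
from cryptomics.simulate import default_sim_config, simulate_crypt_experiment


@pytest.fixture(scope="session")
def small_dataset():
    """A modest fully-featured synthetic experiment shared across tests."""
    cfg = default_sim_config(seed=7, cells_per_sample=400, n_genes=600)
    return simulate_crypt_experiment(cfg)


@pytest.fixture()
def tiny_counts():
    counts = np.array([[5, 0], [0, 0], [0, 1]])
    counts[1, 0] = 2  # avoid an all-zero cell
    return CountMatrix(counts=counts, cell_ids=["c1", "c2", "c3"], gene_ids=["g1", "g2"])


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_expression(values, cell_ids=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ExpressionMatrix(
        values,
        cell_ids or [f"c{i}" for i in range(n)],
        gene_ids or [f"g{j}" for j in range(g)],
    )


def make_annotation(cells, sample="s1", condition="CD", cluster="A", **extra):
    tab = pd.DataFrame(
        {"sample": sample, "condition": condition, "cluster": cluster, **extra},
        index=pd.Index(cells, name="cell_id"),
    )
    return CellAnnotation(tab)
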