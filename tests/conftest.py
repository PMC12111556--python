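import numpy as np
import pandas as pd
import pytest

from ctcmark import ExpressionMatrix, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_cfg():
    """A small configuration used across module tests."""
    return SimConfig(seed=1, n_genes=200, n_tumor=10, n_adjacent=10, n_true_deg=20,
                     sc_n_cells=30)


def random_matrix(rng, n_genes=50, n_samples=8, platform="bulk_log"):
    values = rng.normal(5.0, 2.0, size=(n_genes, n_samples))
    if platform == "fpkm":
        values = np.abs(values)
    df = pd.DataFrame(
        values,
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"S{i:03d}" for i in range(n_samples)],
    )
    return ExpressionMatrix(df, platform=platform)
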