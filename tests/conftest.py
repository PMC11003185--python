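import numpy as np
import pandas as pd
import pytest

from cellpool import CoreParams, ExpressionTable, SimConfig, generate_mixture


@pytest.fixture(scope="session")
def mixture_table() -> ExpressionTable:
    """Two well-separated samples of 1,500 cells each, 10 markers, 5 types."""
    return generate_mixture(SimConfig(n_samples=2, cells_per_sample=1500, seed=7))


@pytest.fixture(scope="session")
def default_params() -> CoreParams:
    return CoreParams(gamma=20.0, seed=3)


@pytest.fixture
def tiny_table() -> ExpressionTable:
    """Six cells, one sample, three markers — hand-checkable."""
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "sample_id": "S1",
            "m1": [0.0, 0.1, 0.2, 5.0, 5.1, 5.2],
            "m2": [1.0, 1.1, 0.9, 3.0, 3.1, 2.9],
            "m3": [0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
        }
    )
    return ExpressionTable(df, ["m1", "m2", "m3"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
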