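import numpy as np
import pandas as pd
import pytest
from anndata import AnnData


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_norm_adata(rng):
    """30 cells x 20 genes of log-normalized-scale expression."""
    X = rng.gamma(2.0, 1.0, size=(30, 20))
    return AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(30)]),
        var=pd.DataFrame(index=[f"g{j}" for j in range(20)]),
    )


@pytest.fixture
def toy_records():
    """Six-subject survival table with one censored observation per group."""
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 1, 0],
            "age": [60.0, 62.0, 58.0, 70.0, 66.0, 64.0],
        },
        index=[f"P{i}" for i in range(6)],
    )
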