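import numpy as np
import pandas as pd
import pytest

import absgsea as a


@pytest.fixture(scope="session")
def small_study():
    """A modest simulated study with correlated null sets, reused by tests
    that only need plausible input data."""
    return a.simulate_study(
        n_genes=600,
        n_sets=6,
        set_size=50,
        n1=3,
        n2=3,
        correlation=0.4,
        seed=11,
    )


@pytest.fixture()
def toy_matrix():
    """4 genes x 6 samples with a clear group difference in gene g1."""
    data = np.array(
        [
            [30, 34, 32, 10, 12, 11],
            [20, 22, 21, 20, 23, 19],
            [5, 6, 7, 6, 5, 7],
            [100, 110, 90, 95, 105, 108],
        ],
        dtype=float,
    )
    return pd.DataFrame(
        data,
        index=["g1", "g2", "g3", "g4"],
        columns=[f"s{i}" for i in range(6)],
    )


@pytest.fixture()
def toy_groups():
    return ["A", "A", "A", "B", "B", "B"]
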