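import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ciliatecomm.datasets import composition_community, composition_table
from ciliatecomm.tables import AbundanceTable

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def table2():
    return composition_table()


@pytest.fixture(scope="session")
def basin_community():
    """Species-level expansion of the published composition table."""
    return composition_community()


@pytest.fixture
def toy_abundance():
    """Six samples over two ecosystems/two seasons, five species."""
    counts = pd.DataFrame(
        [
            [10, 5, 0, 1, 0],
            [8, 6, 1, 0, 0],
            [12, 4, 0, 2, 0],
            [0, 1, 9, 7, 3],
            [1, 0, 11, 5, 4],
            [0, 0, 10, 6, 5],
        ],
        index=[f"s{i}" for i in range(1, 7)],
        columns=[f"sp{j}" for j in range(1, 6)],
    )
    meta = pd.DataFrame(
        {
            "ecosystem": ["grassland"] * 3 + ["wetland"] * 3,
            "season": ["spring", "summer", "autumn"] * 2,
            "latitude": [29.0, 29.01, 29.02, 29.2, 29.21, 29.22],
            "longitude": [88.6, 88.61, 88.62, 88.8, 88.81, 88.82],
            "altitude": [4000.0] * 3 + [3900.0] * 3,
        },
        index=counts.index,
    )
    return AbundanceTable(counts, metadata=meta)
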