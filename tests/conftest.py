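import numpy as np
import pandas as pd
import pytest

from smrlink.io import CountMatrix, SMREventTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_events():
    return SMREventTable(
        pd.DataFrame(
            {
                "cell_id": ["c1", "c2", "c3"],
                "sample_id": ["s1", "s1", "s1"],
                "buoyant_mass": [60.1, 72.4, 55.0],
                "stiffness": [1.1, 0.9, 1.3],
                "volume": [1000.0, 1200.0, 900.0],
            }
        )
    )


@pytest.fixture
def small_matrix():
    counts = np.array(
        [
            [3, 0, 1, 5],
            [0, 2, 0, 0],
            [1, 1, 1, 1],
            [0, 0, 4, 2],
            [9, 3, 0, 7],
        ]
    )
    return CountMatrix(
        genes=["MT-CO1", "ACTB", "CD19", "CCND1", "MKI67"],
        cells=["c1", "c2", "c3", "c4"],
        counts=counts,
        mito_genes=["MT-CO1"],
    )
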