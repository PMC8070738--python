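import numpy as np
import pandas as pd
import pytest

from esterodeg import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_count_matrix():
    """4 genes x 4 samples (2 strains x 2 replicates), hand-sized."""
    counts = pd.DataFrame(
        {
            "wt_1": [10, 0, 100, 5],
            "wt_2": [12, 0, 90, 6],
            "mut_1": [40, 0, 95, 5],
            "mut_2": [44, 0, 105, 7],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    lengths = pd.Series([1000, 500, 2000, 800], index=counts.index, name="length_bp")
    design = {"wt_1": "wt", "wt_2": "wt", "mut_1": "mut", "mut_2": "mut"}
    return CountMatrix(counts=counts, gene_lengths=lengths, design=design)
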