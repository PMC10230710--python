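import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_variant_table():
    return pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(6)],
            "chrom": ["chr1"] * 6,
            "pos": [100, 200, 300, 400, 500, 600],
            "maf": [0.5, 0.3, 0.2, 0.5, 0.4, 0.25],
        }
    )
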