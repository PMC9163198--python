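import numpy as np
import pandas as pd
import pytest

from commsync.community_data import AbundanceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_matrix(rng):
    """A 24-month, 5-species matrix of random counts with some zeros."""
    vals = rng.poisson(8.0, size=(24, 5)).astype(float)
    vals[rng.random(vals.shape) < 0.2] = 0.0
    return AbundanceMatrix.from_values(vals, list("ABCDE"), start="1990-01")


@pytest.fixture
def long_records(rng):
    """Raw long-format records with repeated counts within months."""
    rows = []
    for year in (1990, 1991):
        for month in range(1, 13):
            for sp in "ABC":
                for _ in range(rng.integers(0, 3)):
                    rows.append((year, month, sp, int(rng.integers(0, 30))))
    return pd.DataFrame(rows, columns=["year", "month", "species", "count"])
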