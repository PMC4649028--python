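import numpy as np
import pandas as pd
import pytest

from soilnet.synthetic_data import worked_micro_example
from soilnet.tables_io import CountTable, SampleMetadata


@pytest.fixture(scope="session")
def micro():
    """Hand-sized 12 OTU x 18 sample fixture with designed outcomes."""
    return worked_micro_example()


@pytest.fixture()
def design18_meta(micro):
    return micro.metadata


def random_count_table(rng, n_otus=50, n_samples=18, max_count=40) -> CountTable:
    counts = rng.integers(0, max_count, size=(n_otus, n_samples))
    # sprinkle zeros so presence patterns vary
    counts[rng.random(counts.shape) < 0.3] = 0
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"Otu{i:03d}" for i in range(n_otus)],
            columns=[f"S{j:02d}" for j in range(n_samples)],
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
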