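import numpy as np
import pandas as pd
import pytest

from methylchrom.simulate import simulate_dataset, simulate_genome, small_config


@pytest.fixture(scope="session")
def small_ds():
    """One 400 kb chromosome, full feature complement, seed 11."""
    return simulate_dataset(small_config(seed=11))


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(small_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chrom="chr1", max_pos=10_000, max_len=400):
    starts = rng.integers(0, max_pos - max_len, n)
    lengths = rng.integers(1, max_len, n)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + lengths})
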