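import numpy as np
import pandas as pd
import pytest

from tempopool.pool import PoolSample
from tempopool.synthetic import default_world, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic two-epoch dataset shared across tests."""
    world = default_world(seed=7, n_snps=2000)
    return generate_dataset(world, ne_local=9500)


def make_pool(
    pool_id="p1",
    season="fall",
    location="L1",
    n_flies=40,
    n_eff=40.0,
    positions=(100, 200, 300),
    chrom="2R",
    ref_counts=(10, 10, 10),
    alt_counts=(5, 5, 5),
):
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": "A",
            "alt": "T",
            "ref_count": np.asarray(ref_counts, dtype=np.int64),
            "alt_count": np.asarray(alt_counts, dtype=np.int64),
        }
    )
    return PoolSample(pool_id, season, location, n_flies, n_eff, sites)
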