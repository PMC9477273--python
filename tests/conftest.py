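import numpy as np
import pytest

import cleavekit as ck


@pytest.fixture(scope="session")
def small_library():
    return ck.generate_library(30, n_references=4, n_amplicons=2, seed=11)


@pytest.fixture(scope="session")
def small_compounds():
    return ck.generate_compound_library(100, seed=12)


@pytest.fixture(scope="session")
def toy_design(small_compounds):
    """64 compounds, 4 partitions of 8 pools (pool size 8)."""
    return ck.design_pools(
        small_compounds[:64], n_partitions=4, pool_size=8, seed=13
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
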