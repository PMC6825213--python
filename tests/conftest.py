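import numpy as np
import pandas as pd
import pytest

from bctrace import (
    BarcodeLibrary,
    SimConfig,
    make_benchmark_dataset,
)


@pytest.fixture(scope="session")
def small_library() -> BarcodeLibrary:
    return BarcodeLibrary(
        ("BC01", "BC02", "BC03"),
        (
            "ACGTACGTACGTACGTACGT",
            "TTTTCCCCGGGGAAAATTTT",
            "GATCGATCGATCGATCGATC",
        ),
    )


@pytest.fixture(scope="session")
def benchmark():
    """One seeded benchmark study (NT + Doxo arms) shared across tests."""
    config = SimConfig(seed=1, n_clones=250)
    return make_benchmark_dataset(config, conditions=("NT", "Doxo"))


@pytest.fixture(scope="session")
def benchmark_full():
    """Seeded benchmark with every treatment arm, including DAC combination."""
    config = SimConfig(seed=1, n_clones=250)
    return make_benchmark_dataset(config)


def random_profile(rng: np.random.Generator, n: int, prefix: str = "BC") -> pd.Series:
    x = rng.dirichlet(np.ones(n))
    return pd.Series(x, index=[f"{prefix}{i:03d}" for i in range(n)])
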