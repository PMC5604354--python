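import numpy as np
import pytest

from torsionnet.synth import generate_dataset


@pytest.fixture(scope="session")
def tiny_proteins():
    """Ten short synthetic proteins shared by fast tests."""
    return generate_dataset(10, (30, 60), seed=11)


@pytest.fixture(scope="session")
def benchmark_result():
    """The full four-architecture benchmark, trained once per session."""
    from torsionnet.harness import benchmark

    return benchmark(seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
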