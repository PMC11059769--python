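import numpy as np
import pytest

from mbdetect.detection import run_phantom_benchmark
from mbdetect.phantom import generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Small mixed phantom dataset shared across fast unit tests."""
    return generate_dataset(8, 8, image_size=64, rng_seed=42)


@pytest.fixture(scope="session")
def benchmark():
    """The scaled train-on-normal benchmark (200 train, 100+100 test).

    Trained once per session; several tests inspect its history, scores
    and threshold from different angles.
    """
    return run_phantom_benchmark(seed=0)
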