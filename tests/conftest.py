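import numpy as np
import pytest

from dscnl.datasets import (NoiseSpec, generate_synthetic_dataset,
                            inject_symmetric_noise)

PARTITION = [{0, 1}, {2, 3}, {4, 5}, {6, 7}]


def make_stream(noise_rate: float, seed: int, n_per_class: int = 200,
                n_test_per_class: int = 50, image_size: int = 32):
    """Standard desk-scale benchmark stream: 8 separable classes, symmetric
    noise on the train split only, 4 binary tasks."""
    train = generate_synthetic_dataset(8, n_per_class, image_size, 1.0,
                                       seed=seed)
    test = generate_synthetic_dataset(8, n_test_per_class, image_size, 1.0,
                                      seed=seed + 10_000, split="test")
    if noise_rate > 0:
        train = inject_symmetric_noise(train, NoiseSpec(rate=noise_rate,
                                                        seed=seed))
    return train, test


@pytest.fixture(scope="session")
def clean_stream():
    return make_stream(0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_stream():
    """One rho=0.3 stream shared across read-only tests."""
    return make_stream(0.3, seed=0)
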