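import numpy as np
import pytest

from copulagraph import (
    MixedDataset,
    VariableSpec,
    mixed_specs,
    random_sparse_precision,
    sample_copula_data,
)


@pytest.fixture
def continuous_dataset():
    """Small all-continuous Gaussian dataset with known latent structure."""
    rng = np.random.default_rng(42)
    truth = random_sparse_precision(5, 0.3, (0.3, 0.4), "random", seed=7)
    data = sample_copula_data(truth, 200, seed=8)
    return data, truth


@pytest.fixture
def ordinal_dataset():
    """3-variable chain of 3-level ordinals, n = 300."""
    specs = mixed_specs(3, "ordinal", 3)
    truth = random_sparse_precision(3, 1.0, (0.3, 0.4), "chain", seed=0,
                                    specs=specs)
    data = sample_copula_data(truth, 300, seed=1)
    return data, truth


@pytest.fixture
def tiny_dataset():
    """Hand-built 4x3 mixed table with one missing cell."""
    specs = [
        VariableSpec("score", "ordinal", levels=[0, 1, 2]),
        VariableSpec("flag", "binary", levels=["no", "yes"]),
        VariableSpec("intake", "continuous"),
    ]
    values = np.array([
        [0, 0, 1.5],
        [1, 1, np.nan],
        [2, 0, 3.0],
        [1, 1, 2.2],
    ])
    mask = np.zeros((4, 3), dtype=bool)
    mask[1, 2] = True
    return MixedDataset(values, specs, mask)
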