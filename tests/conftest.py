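import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_table():
    """Small abundance table with one pair of proportional taxa."""
    return pd.DataFrame(
        {
            "S1": [0.0, 0.0, 5.0, 1.0],
            "S2": [1.0, 2.0, 3.0, 1.0],
            "S3": [2.0, 4.0, 1.0, 1.0],
        },
        index=pd.Index(["up_a", "up_b", "down", "flat"], name="taxon"),
    )


def random_table(rng, n_taxa=12, n_samples=6, zero_rate=0.2):
    values = rng.gamma(0.8, 10.0, size=(n_taxa, n_samples))
    values[rng.random(values.shape) < zero_rate] = 0.0
    return pd.DataFrame(
        values,
        index=[f"T{i}" for i in range(n_taxa)],
        columns=[f"S{j}" for j in range(n_samples)],
    )


def naive_slope_distance(alpha, beta):
    """Independent oracle: literal double loop over all ordered pairs."""
    n = len(alpha)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += abs((alpha[j] - alpha[i]) - (beta[j] - beta[i]))
    return total
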