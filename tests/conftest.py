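import numpy as np
import pandas as pd
import pytest

from nerclust import OccurrenceMatrix


def block_matrix(sizes, within=0.1, between=0.9, noise=0.0, rng=None):
    """Square dissimilarity matrix with planted blocks (plus optional noise)."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise:
        eps = rng.uniform(-noise, noise, size=(n, n))
        eps = (eps + eps.T) / 2
        d = np.clip(d + eps, 0.01, 1.0)
    np.fill_diagonal(d, 0.0)
    return d, labels


@pytest.fixture
def two_block():
    d, labels = block_matrix([4, 4])
    return d, labels


@pytest.fixture
def occurrence_small():
    # 5 species x 4 sites, counts
    df = pd.DataFrame(
        [[0, 3, 1, 7], [2, 0, 0, 1], [5, 5, 0, 0], [0, 1, 1, 0], [1, 0, 2, 0]],
        index=[f"sp{i}" for i in range(1, 6)],
        columns=["A", "B", "C", "D"],
    )
    return OccurrenceMatrix(df)
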