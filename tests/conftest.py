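import numpy as np
import pytest

from dockfuse import ScoreMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_matrix():
    """2 actives, 2 inactives, 3 structures; all-negative scores."""
    return ScoreMatrix(
        compound_ids=["A1", "A2", "I1", "I2"],
        labels=[1, 1, 0, 0],
        structure_ids=["S1", "S2", "S3"],
        scores=[
            [-10.0, -9.5, -11.0],
            [-9.0, -8.0, -9.5],
            [-5.0, -6.0, -4.5],
            [-4.0, -5.5, -5.0],
        ],
    )


def random_negative_matrix(rng, n=50, k=5, n_act=10):
    """Random all-negative score matrix with labelled actives first."""
    scores = -rng.uniform(1.0, 15.0, size=(n, k))
    labels = np.zeros(n, dtype=int)
    labels[:n_act] = 1
    return ScoreMatrix(
        compound_ids=[f"C{i}" for i in range(n)],
        labels=labels,
        structure_ids=[f"S{j}" for j in range(k)],
        scores=scores,
    )
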