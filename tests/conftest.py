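import numpy as np
import pytest

from seqentropy import EmbeddingSet


@pytest.fixture
def small_set() -> EmbeddingSet:
    """4 samples, 2 dims, balanced labels."""
    return EmbeddingSet(
        epoch=0,
        sample_ids=("a", "b", "c", "d"),
        labels=np.array([1, 1, 0, 0]),
        features=np.array([[0.0, 0.0], [1.0, 0.5], [3.0, 3.0], [4.0, 3.5]]),
    )


@pytest.fixture
def gaussian_set() -> EmbeddingSet:
    """Two spherical Gaussian classes, positives twice as dispersed."""
    rng = np.random.default_rng(42)
    n = 300
    pos = 2.0 * rng.standard_normal((n, 3))
    neg = rng.standard_normal((n, 3))
    return EmbeddingSet(
        epoch=0,
        sample_ids=tuple(f"s{i}" for i in range(2 * n)),
        labels=np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)],
        features=np.vstack([pos, neg]),
    )
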