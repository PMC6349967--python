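import numpy as np
import pytest

from mlenz.rank_loss import LabelSet
from mlenz.synthetic_data import SimSpec, generate


@pytest.fixture(scope="session")
def worked_example():
    """The printed six-class example: scores and the true set {1, 2}."""
    scores = np.array([0.9, 0.8, 0.3, 0.1, 0.1, 0.1])
    labels = LabelSet({1, 2}, q=6)
    return scores, labels


@pytest.fixture(scope="session")
def small_dataset():
    """A small noiseless synthetic dataset shared across tests."""
    return generate(SimSpec(n=120, seed=7))


def random_label_set(rng: np.random.Generator, q: int, allow_degenerate: bool = False) -> LabelSet:
    if allow_degenerate:
        k = int(rng.integers(0, q + 1))
    else:
        k = int(rng.integers(1, q))
    members = rng.choice(np.arange(1, q + 1), size=k, replace=False).tolist()
    return LabelSet(members, q=q)
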