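import numpy as np
import pytest

from csbboost import LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240302)


def make_imbalanced(n0: int, n1: int, seed: int = 0, d: int = 2,
                    spread: float = 4.0) -> LabeledDataset:
    """Two loose Gaussian classes with n0 negatives and n1 positives."""
    r = np.random.default_rng(seed)
    X0 = r.normal(0.0, 1.0, size=(n0, d))
    X1 = r.normal(spread, 1.0, size=(n1, d))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    perm = r.permutation(n0 + n1)
    return LabeledDataset(X[perm], y[perm])


@pytest.fixture
def case_sizes():
    """Cluster sizes of the worked clinical example: 695 = 89+550+56, 55 = 44+11."""
    return {"majority": (89, 550, 56), "minority": (44, 11), "N": 750}
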