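import numpy as np
import pytest

import chimpnet as cn
from chimpnet.matrix import DyadMatrix


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the shipped defaults (seed 0)."""
    return cn.generate_dataset(cn.CommunityConfig(seed=0))


@pytest.fixture(scope="session")
def default_counts(default_dataset):
    _attrs, _model, scans, _events = default_dataset
    return cn.count_dyads(scans)


def random_matrix(rng: np.random.Generator, n: int = 12, label: str = "m",
                  scale: float = 60.0, missing: float = 0.0) -> DyadMatrix:
    """Random nonnegative weighted matrix, optionally with missing cells."""
    vals = rng.uniform(0.0, scale, size=(n, n))
    if missing > 0:
        mask = rng.random((n, n)) < missing
        vals[mask] = np.nan
    ids = [f"N{i:02d}" for i in range(n)]
    return DyadMatrix(ids, vals, label=label)
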