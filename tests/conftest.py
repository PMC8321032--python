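import numpy as np
import pandas as pd
import pytest

import morphpca as mp


@pytest.fixture(scope="session")
def tiny_data():
    """Small synthetic cohort (3 landmarks, 90 subjects) with ground truth."""
    spec = mp.tiny_spec(seed=42)
    dataset, truth = mp.simulate(spec)
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_results(tiny_data):
    dataset, _ = tiny_data
    return mp.MultilevelPCA(dataset).fit(retain=(2, 2, 1, 9))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def balanced_dataset(n_per_cell: int, seed: int, k: int = 3) -> mp.ShapeDataset:
    """Plain Gaussian dataset with every factor cell filled equally."""
    rng = np.random.default_rng(seed)
    cells = [
        (s, a, x)
        for s in ("none", "t1_only", "t1_t2")
        for a in ("none", "t1_only", "t1_t2")
        for x in ("male", "female")
    ]
    rows, smoking, alcohol, sex = [], [], [], []
    for s, a, x in cells:
        rows.append(rng.standard_normal((n_per_cell, 3 * k)))
        smoking += [s] * n_per_cell
        alcohol += [a] * n_per_cell
        sex += [x] * n_per_cell
    X = np.vstack(rows)
    names = tuple(f"lm{i}" for i in range(k))
    labels = pd.DataFrame({"smoking": smoking, "alcohol": alcohol, "sex": sex})
    ids = [f"s{i}" for i in range(len(labels))]
    return mp.ShapeDataset(X, labels, ids, names)
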