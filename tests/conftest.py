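import numpy as np
import pandas as pd
import pytest

from guttide.containers import AsvTable
from guttide.io import parse_tree


@pytest.fixture
def hand_tree():
    """Three-tip tree with known patristic distances: d(A,B)=2, d(A,C)=4."""
    return parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        [[5, 0, 3, 1], [2, 2, 0, 4], [1, 7, 1, 0]],
        index=["S1", "S2", "S3"],
        columns=["A", "B", "C", "D"],
    )
    return AsvTable(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_table(rng, n_samples, n_taxa, depth=2000):
    """Random multinomial count table with lognormal sample profiles."""
    probs = rng.lognormal(0, 1, size=(n_samples, n_taxa))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p) for p in probs])
    # guarantee non-empty samples
    counts[counts.sum(axis=1) == 0, 0] = 1
    return AsvTable(
        pd.DataFrame(
            counts,
            index=[f"S{i}" for i in range(n_samples)],
            columns=[f"T{j}" for j in range(n_taxa)],
        )
    )
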