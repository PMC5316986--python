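import numpy as np
import pandas as pd
import pytest

from floraltraits import (
    DistanceMatrix,
    TraitTable,
    euclidean_matrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def worked_permanova_dm():
    """Four 1-D samples (0, 1 | 3, 4) as a Euclidean distance matrix."""
    return euclidean_matrix(np.array([[0.0], [1.0], [3.0], [4.0]]),
                            ["s1", "s2", "s3", "s4"])


@pytest.fixture
def small_table():
    values = np.array(
        [
            [1.0, 0.0, 3.0],
            [0.0, 2.0, 2.0],
            [2.0, 2.0, 4.0],
            [1.0, 1.0, 1.0],
        ]
    )
    meta = pd.DataFrame(
        {"species": ["sp1", "sp1", "sp2", "sp2"],
         "bee_group": ["g1", "g1", "g2", "g2"]},
        index=["a", "b", "c", "d"],
    )
    return TraitTable(values, ["a", "b", "c", "d"], ["v1", "v2", "v3"], meta)


@pytest.fixture
def three_leaf_dm():
    """d(A,B)=2, d(A,C)=d(B,C)=6: the worked UPGMA instance."""
    d = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]])
    return DistanceMatrix(d, ["A", "B", "C"])


def random_distance_matrix(rng, n, labels=None):
    """Random metric-free symmetric dissimilarity matrix for clustering tests."""
    m = rng.uniform(0.1, 1.0, size=(n, n))
    d = (m + m.T) / 2.0
    np.fill_diagonal(d, 0.0)
    if labels is None:
        labels = [f"L{i:02d}" for i in range(n)]
    return DistanceMatrix(d, labels)
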