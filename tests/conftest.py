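import numpy as np
import pytest

from isotraj.containers import Embedding, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4 genes x 5 cells, hand-pickable values."""
    values = np.array(
        [
            [0.0, 0.0, 0.0, 0.0, 0.0],  # never expressed
            [5.0, 5.0, 5.0, 5.0, 5.0],  # constant nonzero
            [1.0, 2.0, 3.0, 4.0, 5.0],  # varying
            [0.0, 0.0, 0.0, 0.0, 9.0],  # expressed in 1/5 cells
        ]
    )
    return ExpressionMatrix(
        values,
        gene_ids=[f"g{i}" for i in range(4)],
        cell_ids=[f"c{i}" for i in range(5)],
        is_log=True,
    )


def make_embedding(coords, space="tsne"):
    coords = np.asarray(coords, dtype=float)
    ids = [f"cell_{i}" for i in range(coords.shape[0])]
    return Embedding(coords, space, ids)


@pytest.fixture
def three_blobs(rng):
    """Three well-separated 2-D Gaussian blobs with labels."""
    centers = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 30.0]])
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, 1.0, size=(50, 2)))
        labels += [i] * 50
    return np.vstack(pts), np.array(labels)
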