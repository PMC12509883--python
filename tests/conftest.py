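import numpy as np
import pytest

from msclust.graph_core import CellGraph, ExpressionMatrix, SimilarityMatrix


def graph_from_edges(n, edges, weights=None):
    edges = [(min(a, b), max(a, b)) for a, b in edges]
    u = np.array([e[0] for e in edges], dtype=np.int64)
    v = np.array([e[1] for e in edges], dtype=np.int64)
    w = np.ones(len(edges)) if weights is None else np.asarray(weights, float)
    return CellGraph([f"c{i}" for i in range(n)], u, v, w)


def clique_edges(nodes):
    nodes = list(nodes)
    return [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]


def two_blob_expression(n_per_blob=20, n_features=60, sep=6.0, noise=0.3, seed=0):
    """Two well-separated Gaussian blobs of cells; blob id = cell index // n_per_blob."""
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((2, n_features)) * sep
    cells = np.vstack(
        [centers[b] + noise * rng.standard_normal((n_per_blob, n_features)) for b in (0, 1)]
    )
    values = cells.T  # features x cells
    n = 2 * n_per_blob
    return ExpressionMatrix(
        values, [f"g{j}" for j in range(n_features)], [f"c{i}" for i in range(n)]
    )


def random_similarity(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n))
    S = (A + A.T) / 2
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, "pearson_features")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
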