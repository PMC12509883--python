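"""Cell similarity, planar maximally filtered graphs, and basic graph measures.

The locally embedded network machinery rests on three primitives: a cell-cell
similarity matrix, the planar maximally filtered graph (PMFG) that keeps the
highest-similarity links subject to planarity (hence at most ``3(n - 2)`` edges
by Euler's relation), and mean shortest-path distances used by the compactness
statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform

from ._planarity import _pmfg_kernel

logger = logging.getLogger(__name__)

PEARSON_FEATURES = "pearson_features"
EUCLIDEAN_PCS = "euclidean_pcs"


@dataclass
class ExpressionMatrix:
    """Normalized expression values, features x cells, with identifiers.

    ``expressed`` marks entries with value > 0; the per-cell expressed gene
    sets drive the low-similarity screen.
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_feat, n_cells = self.values.shape
        if len(self.feature_ids) != n_feat:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {n_feat} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cells} columns")
        if len(set(self.feature_ids)) != n_feat:
            raise ValueError("duplicate feature ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def expressed(self) -> np.ndarray:
        """Boolean mask of expressed entries (value > 0)."""
        return self.values > 0

    def subset_features(self, rows: np.ndarray) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return ExpressionMatrix(
            self.values[rows],
            [self.feature_ids[r] for r in rows],
            list(self.cell_ids),
        )


@dataclass
class SimilarityMatrix:
    """Symmetric cells x cells similarity.

    Euclidean distances are stored negated so that "larger means closer"
    holds for every metric and downstream neighbor logic stays uniform.
    """

    S: np.ndarray
    metric: str
    higher_is_closer: bool = True

    @property
    def n_cells(self) -> int:
        return self.S.shape[0]


@dataclass
class CellGraph:
    """Undirected weighted graph over cells.

    Edges are stored as parallel arrays ``(u, v, w)`` with ``u < v``; node
    indices refer to positions in ``node_ids``.
    """

    node_ids: list[str]
    edges_u: np.ndarray
    edges_v: np.ndarray
    weights: np.ndarray
    _adj: list[set] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.edges_u = np.asarray(self.edges_u, dtype=np.int64)
        self.edges_v = np.asarray(self.edges_v, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.edges_u >= self.edges_v):
            raise ValueError("edges must satisfy u < v (no self-loops)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("edge weights must be finite")
        pairs = set(zip(self.edges_u.tolist(), self.edges_v.tolist()))
        if len(pairs) != len(self.edges_u):
            raise ValueError("duplicate edges")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges_u)

    def adjacency(self) -> list[set]:
        """Neighbor sets per node (cached)."""
        if self._adj is None:
            adj: list[set] = [set() for _ in range(self.n_nodes)]
            for u, v in zip(self.edges_u.tolist(), self.edges_v.tolist()):
                adj[u].add(v)
                adj[v].add(u)
            self._adj = adj
        return self._adj

    def csr(self) -> csr_matrix:
        n = self.n_nodes
        row = np.concatenate([self.edges_u, self.edges_v])
        col = np.concatenate([self.edges_v, self.edges_u])
        dat = np.ones(2 * self.n_edges)
        return csr_matrix((dat, (row, col)), shape=(n, n))

    def subgraph(self, nodes: np.ndarray) -> tuple["CellGraph", np.ndarray]:
        """Induced subgraph; returns the graph (re-indexed) and the node list."""
        nodes = np.asarray(sorted(nodes), dtype=np.int64)
        local = -np.ones(self.n_nodes, dtype=np.int64)
        local[nodes] = np.arange(len(nodes))
        mask = (local[self.edges_u] >= 0) & (local[self.edges_v] >= 0)
        return (
            CellGraph(
                [self.node_ids[i] for i in nodes],
                local[self.edges_u[mask]],
                local[self.edges_v[mask]],
                self.weights[mask],
            ),
            nodes,
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(
            zip(self.edges_u.tolist(), self.edges_v.tolist(), self.weights.tolist())
        )
        return g


def compute_similarity(
    expr: ExpressionMatrix,
    metric: str = PEARSON_FEATURES,
    reduced: np.ndarray | None = None,
) -> SimilarityMatrix:
    """Cell-cell similarity: Pearson correlation over features, or negated
    Euclidean distance over a reduced (cells x components) embedding.

    Zero-variance cells under Pearson get the matrix minimum similarity and a
    logged warning rather than NaNs.
    """
    if metric == PEARSON_FEATURES:
        if expr.n_features < 3:
            raise ValueError("pearson_features requires at least 3 features")
        X = expr.values
        sd = X.std(axis=0)
        degenerate = sd == 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            S = np.corrcoef(X, rowvar=False)
        if degenerate.any():
            logger.warning(
                "%d zero-variance cell(s) under pearson; similarities set to minimum",
                int(degenerate.sum()),
            )
            floor = np.nanmin(S)
            S[degenerate, :] = floor
            S[:, degenerate] = floor
        np.fill_diagonal(S, 1.0)
        S = (S + S.T) / 2.0
        return SimilarityMatrix(S, metric, higher_is_closer=True)
    if metric == EUCLIDEAN_PCS:
        if reduced is None:
            raise ValueError("euclidean_pcs requires a reduced matrix")
        reduced = np.asarray(reduced, dtype=float)
        if reduced.shape[0] != expr.n_cells:
            raise ValueError("reduced matrix rows must match cell count")
        S = -squareform(pdist(reduced, metric="euclidean"))
        return SimilarityMatrix(S, metric, higher_is_closer=True)
    raise ValueError(f"unknown metric: {metric}")


def _pmfg_edges(sim: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy PMFG on a dense local similarity matrix (indices 0..n-1).

    Candidate edges are sorted by similarity descending with lexicographic
    (min, max) tie-break; each is inserted iff planarity is preserved;
    insertion stops at the Euler bound 3(n - 2).
    """
    n = sim.shape[0]
    if n < 3:
        raise ValueError("PMFG needs at least 3 nodes")
    iu, ju = np.triu_indices(n, k=1)
    w = sim[iu, ju]
    if not np.all(np.isfinite(w)):
        raise ValueError("similarities must be finite")
    # stable ordering: descending weight, then (i, j) lexicographic
    order = np.lexsort((ju, iu, -w))
    cu = iu[order].astype(np.int64)
    cv = ju[order].astype(np.int64)
    if n <= 4:  # complete graphs up to K4 are planar
        k = min(3 * (n - 2), len(cu))
        return cu[:k], cv[:k]
    m, keep = _pmfg_kernel(np.int64(n), cu, cv)
    return cu[keep], cv[keep]


def pmfg(S_sub: SimilarityMatrix | np.ndarray, node_ids: list[str] | None = None) -> CellGraph:
    """Planar maximally filtered graph over a (restricted) similarity matrix."""
    sim = S_sub.S if isinstance(S_sub, SimilarityMatrix) else np.asarray(S_sub, float)
    n = sim.shape[0]
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    u, v = _pmfg_edges(sim)
    return CellGraph(node_ids, u, v, sim[u, v] if len(u) else np.array([]))


def mean_spd(g: CellGraph, members: np.ndarray | None = None) -> float:
    """Mean unweighted shortest-path (hop) distance over all unordered pairs
    of ``members`` in the induced subgraph.  Errors if that subgraph is
    disconnected (reporting its components)."""
    if members is None:
        sub = g
    else:
        sub, _ = g.subgraph(np.asarray(members))
    n = sub.n_nodes
    if n < 2:
        raise ValueError("mean SPD needs at least 2 members")
    adj = sub.csr()
    ncomp, labels = connected_components(adj, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"induced subgraph is disconnected: {ncomp} components with sizes "
            f"{sorted(sizes.tolist(), reverse=True)}"
        )
    D = shortest_path(adj, method="D", directed=False, unweighted=True)
    iu = np.triu_indices(n, k=1)
    return float(D[iu].mean())
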