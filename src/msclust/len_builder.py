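"""Locally embedded network (LEN) construction.

Per cell, candidate neighborhoods of growing size k are embedded as planar
maximally filtered graphs until the focal cell's adjacency saturates (the
embedded neighbors).  The union of all per-cell stars forms the raw network,
which is then screened for low-quality links in two passes: a low-similarity
screen against a LOESS trend of similarity on the expressed-gene Jaccard
index, and a low-centrality screen that contests weak links by the shared
nearest-neighbor ratio.

The whole module is deterministic: no randomness enters LEN construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .graph_core import (
    CellGraph,
    ExpressionMatrix,
    SimilarityMatrix,
    compute_similarity,
    _pmfg_edges,
)

logger = logging.getLogger(__name__)

REASON_LOW_SIMILARITY = "low_similarity"
REASON_LOW_CENTRALITY = "low_centrality"


@dataclass
class NeighborResult:
    """Embedded neighbors of one cell: the saturated PMFG adjacency set."""

    cell: int
    neighbors: frozenset
    k_prime: int
    trace: dict | None = None  # per-k adjacency sets, kept only on request


@dataclass
class ScreenParams:
    """Link-screening parameters.

    ``sd_multiplier`` is the outlier threshold in residual standard
    deviations below the LOESS trend; ``contest_quantile`` is the fraction
    of lowest-similarity links contested in the centrality screen;
    ``min_degree`` floors node degrees so screening never isolates a cell.
    """

    loess_span: float = 0.75
    sd_multiplier: float = 2.0
    contest_quantile: float = 0.25
    min_degree: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if not 0 < self.contest_quantile < 1:
            raise ValueError("contest_quantile must be in (0, 1)")


@dataclass
class EdgeDiagnostics:
    """Per-edge screening diagnostics as a table."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cell_i", "cell_j", "S", "J", "M", "removed", "reason"]
        )
    )

    def to_csv(self, path, sep="\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


def default_k_max(n_cells: int) -> int:
    """Candidate-count cap: honors the scan range [3, sqrt(N)] while keeping
    cost near the k' ~ log(N) saturation scale."""
    return min(
        int(math.ceil(math.sqrt(n_cells))),
        max(10, 3 * int(math.ceil(math.log(n_cells)))),
    )


def embedded_neighbors(
    i: int,
    S: SimilarityMatrix,
    k_max: int | None = None,
    plateau_len: int = 2,
    keep_trace: bool = False,
    _order: np.ndarray | None = None,
) -> NeighborResult:
    """Scan k = 3..k_max; at each k embed cell ``i`` with its k most similar
    cells as a PMFG and record the cells adjacent to ``i``.  The scan stops
    when the adjacency set is unchanged for ``plateau_len`` consecutive k,
    returning that set and the k at which the plateau began."""
    n = S.n_cells
    if n - 1 < 3:
        raise ValueError("embedded neighbors need at least 3 other cells")
    if k_max is None:
        k_max = default_k_max(n)
    k_max = max(3, min(k_max, n - 1))
    if _order is None:
        order = np.argsort(-S.S[i], kind="stable")
        order = order[order != i]
    else:
        order = _order
    trace: dict = {}
    prev: frozenset | None = None
    run = 0
    sim = S.S
    for k in range(3, k_max + 1):
        nodes = np.empty(k + 1, dtype=np.int64)
        nodes[0] = i
        nodes[1:] = order[:k]
        sub = sim[np.ix_(nodes, nodes)]
        eu, ev = _pmfg_edges(sub)
        mask = (eu == 0) | (ev == 0)
        adj = frozenset(nodes[eu[mask] + ev[mask]].tolist())
        if keep_trace:
            trace[k] = adj
        if adj == prev:
            run += 1
        else:
            run = 1
            prev = adj
        if run >= plateau_len:
            return NeighborResult(i, adj, k - plateau_len + 1, trace or None)
    if k_max - 3 + 1 > plateau_len:
        logger.debug("cell %d: no neighbor plateau by k_max=%d", i, k_max)
    return NeighborResult(i, prev if prev is not None else frozenset(), k_max, trace or None)


def assemble_len(results: list[NeighborResult], S: SimilarityMatrix, node_ids=None) -> CellGraph:
    """Union of all per-cell stars to their embedded neighbors, weighted by
    similarity.  An edge is present iff at least one endpoint lists the
    other as an embedded neighbor."""
    n = S.n_cells
    if len(results) != n:
        raise ValueError("need one NeighborResult per cell")
    pairs = set()
    for r in results:
        for j in r.neighbors:
            pairs.add((r.cell, j) if r.cell < j else (j, r.cell))
    pairs = sorted(pairs)
    u = np.array([p[0] for p in pairs], dtype=np.int64)
    v = np.array([p[1] for p in pairs], dtype=np.int64)
    if node_ids is None:
        node_ids = [str(k) for k in range(n)]
    return CellGraph(node_ids, u, v, S.S[u, v] if len(pairs) else np.array([]))


def _expressed_jaccard(expr: ExpressionMatrix, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    E = expr.expressed
    n_per_cell = E.sum(axis=0)
    inter = (E[:, u] & E[:, v]).sum(axis=0)
    union = n_per_cell[u] + n_per_cell[v] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    return J


def similarity_screen(
    g: CellGraph,
    expr: ExpressionMatrix,
    p: ScreenParams | None = None,
) -> tuple[CellGraph, EdgeDiagnostics]:
    """Remove links whose similarity is an outlier below the LOESS trend of
    similarity on the expressed-gene Jaccard index J_ij.

    The threshold is the fitted mean minus ``sd_multiplier`` global residual
    standard deviations.  Pairs with an undefined J (no expressed gene in
    either cell) are removed outright.
    """
    if p is None:
        p = ScreenParams()
    u, v, w = g.edges_u, g.edges_v, g.weights
    if g.n_edges < 10:
        logger.warning("similarity screen skipped: only %d edges", g.n_edges)
        tab = pd.DataFrame(
            {
                "cell_i": [g.node_ids[a] for a in u],
                "cell_j": [g.node_ids[b] for b in v],
                "S": w,
                "J": _expressed_jaccard(expr, u, v) if g.n_edges else [],
                "M": np.nan,
                "removed": False,
                "reason": "",
            }
        )
        return g, EdgeDiagnostics(tab)
    J = _expressed_jaccard(expr, u, v)
    defined = ~np.isnan(J)
    fit = np.full(len(w), np.nan)
    if defined.sum() >= 10 and np.ptp(J[defined]) > 0:
        fit[defined] = lowess(
            w[defined],
            J[defined],
            frac=p.loess_span,
            return_sorted=False,
            delta=0.01 * np.ptp(J[defined]),
        )
    else:
        fit[defined] = w[defined].mean()
    resid = w - fit
    sd = float(np.nanstd(resid))
    scale = max(1.0, float(np.nanmax(np.abs(w))))
    if sd <= 1e-9 * scale:  # numerically constant scatter: nothing to flag
        removed = np.zeros(len(w), dtype=bool)
    else:
        removed = defined & (w < fit - p.sd_multiplier * sd)
    removed |= ~defined  # undefined J: no expressed support for the link
    tab = pd.DataFrame(
        {
            "cell_i": [g.node_ids[a] for a in u],
            "cell_j": [g.node_ids[b] for b in v],
            "S": w,
            "J": J,
            "M": np.nan,
            "removed": removed,
            "reason": np.where(removed, REASON_LOW_SIMILARITY, ""),
        }
    )
    keep = ~removed
    out = CellGraph(list(g.node_ids), u[keep], v[keep], w[keep])
    logger.info("similarity screen: %d -> %d edges", g.n_edges, out.n_edges)
    return out, EdgeDiagnostics(tab)


def _snn_ratio(adj_u: set, adj_v: set) -> float:
    inter = len(adj_u & adj_v)
    union = len(adj_u | adj_v)
    return inter / union if union else 0.0


def centrality_screen(
    g: CellGraph,
    p: ScreenParams | None = None,
    caption_rule: bool = False,
) -> tuple[CellGraph, EdgeDiagnostics]:
    """Contest the lowest-similarity quantile of links by the shared
    nearest-neighbor ratio M_ij.

    Contested links are visited in ascending similarity; a link is removed
    iff dropping it strictly increases M_ij (with ``caption_rule=True`` the
    alternative reading: removed iff M_ij does *not* improve) and both
    endpoint degrees stay at or above ``min_degree``.  Removals apply
    immediately and affect subsequent evaluations.
    """
    if p is None:
        p = ScreenParams()
    u, v, w = g.edges_u, g.edges_v, g.weights
    m = g.n_edges
    adj = [set(s) for s in g.adjacency()]
    order = np.lexsort((v, u, w))  # ascending similarity, deterministic ties
    n_contest = int(math.floor(p.contest_quantile * m))
    M_vals = np.full(m, np.nan)
    removed = np.zeros(m, dtype=bool)
    for idx in order[:n_contest]:
        a, b = int(u[idx]), int(v[idx])
        m_with = _snn_ratio(adj[a], adj[b])
        adj[a].discard(b)
        adj[b].discard(a)
        m_without = _snn_ratio(adj[a], adj[b])
        M_vals[idx] = m_with
        improves = m_without > m_with
        drop = (not improves) if caption_rule else improves
        if drop and len(adj[a]) >= p.min_degree and len(adj[b]) >= p.min_degree:
            removed[idx] = True
        else:
            adj[a].add(b)
            adj[b].add(a)
    tab = pd.DataFrame(
        {
            "cell_i": [g.node_ids[a] for a in u],
            "cell_j": [g.node_ids[b] for b in v],
            "S": w,
            "J": np.nan,
            "M": M_vals,
            "removed": removed,
            "reason": np.where(removed, REASON_LOW_CENTRALITY, ""),
        }
    )
    keep = ~removed
    out = CellGraph(list(g.node_ids), u[keep], v[keep], w[keep])
    logger.info("centrality screen: %d -> %d edges", m, out.n_edges)
    return out, EdgeDiagnostics(tab)


def build_len(
    expr: ExpressionMatrix,
    metric: str = "pearson_features",
    params: ScreenParams | None = None,
    reduced: np.ndarray | None = None,
    k_max: int | None = None,
    plateau_len: int = 2,
    caption_rule: bool = False,
    return_diagnostics: bool = False,
    similarity: SimilarityMatrix | None = None,
):
    """Full LEN pipeline: similarity -> per-cell embedding -> union ->
    similarity screen -> centrality screen.  Deterministic for fixed input."""
    if params is None:
        params = ScreenParams()
    S = similarity if similarity is not None else compute_similarity(expr, metric, reduced)
    n = S.n_cells
    if k_max is None:
        k_max = default_k_max(n)
    order_all = np.argsort(-S.S, axis=1, kind="stable")
    results = []
    for i in range(n):
        row = order_all[i]
        results.append(
            embedded_neighbors(
                i, S, k_max=k_max, plateau_len=plateau_len, _order=row[row != i]
            )
        )
    g = assemble_len(results, S, node_ids=list(expr.cell_ids))
    logger.info("assembled LEN: %d cells, %d edges", g.n_nodes, g.n_edges)
    g1, d1 = similarity_screen(g, expr, params)
    g2, d2 = centrality_screen(g1, params, caption_rule=caption_rule)
    if return_diagnostics:
        diag = EdgeDiagnostics(pd.concat([d1.table, d2.table], ignore_index=True))
        return g2, diag
    return g2
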