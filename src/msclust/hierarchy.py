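"""Iterative top-down multiscale clustering (MSC) driver.

Starting from the full LEN, each parent network is split with AdaptSplit;
child clusters are kept only when they improve on the parent in compactness
(mean shortest-path distance scaled by log cluster size to the calibrated
power alpha*) and are significantly coherent under a cell-relabeling
permutation test of intracluster connectivity.  Accepted children are split
recursively; the result is a rooted parent/child cluster hierarchy whose
nodes may nest but whose siblings are disjoint.
"""

from __future__ import annotations

import json
import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptsplit import DEFAULT_GRID, adapt_split
from .graph_core import CellGraph, ExpressionMatrix, mean_spd
from .len_builder import ScreenParams, build_len

logger = logging.getLogger(__name__)


@dataclass
class CompactnessParams:
    """Calibration settings for the compactness scaling exponent alpha."""

    n_sample_nodes: int = 100
    n_layers: int = 3
    alpha_cap: float = 2.0


@dataclass
class ClusterNode:
    id: str
    members: np.ndarray  # global cell indices
    parent: str | None
    gamma_f: float
    compactness: float
    lam: float
    p_conn: float
    level: int


@dataclass
class ClusterHierarchy:
    cell_ids: list[str]
    nodes: dict = field(default_factory=dict)  # id -> ClusterNode
    alpha_star: float = 1.0
    root_compactness: float = math.inf
    graph: CellGraph | None = None

    ROOT = "root"

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def children(self, node_id: str) -> list[str]:
        return [k for k, v in self.nodes.items() if v.parent == node_id]

    def node_ids_breadth_first(self) -> list[str]:
        return list(self.nodes)  # insertion order is breadth-first

    def member_ids(self, node_id: str) -> set:
        return {self.cell_ids[i] for i in self.nodes[node_id].members}

    def to_dict(self) -> dict:
        return {
            "alpha_star": self.alpha_star,
            "root_compactness": self.root_compactness,
            "cells": self.cell_ids,
            "nodes": {
                k: {
                    "parent": v.parent,
                    "members": [self.cell_ids[i] for i in v.members],
                    "gamma_f": v.gamma_f,
                    "compactness": v.compactness,
                    "lambda": v.lam,
                    "p_conn": v.p_conn,
                    "level": v.level,
                }
                for k, v in self.nodes.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def memberships(self) -> pd.DataFrame:
        """Long (cell_id, node_id) table over all overlapping memberships."""
        rows = []
        for k, v in self.nodes.items():
            for i in v.members:
                rows.append((self.cell_ids[i], k))
        return pd.DataFrame(rows, columns=["cell_id", "node_id"])

    def to_newick(self) -> str:
        """Tree topology with compactness values as branch annotations."""

        def rec(node_id: str) -> str:
            kids = self.children(node_id)
            h = (
                self.root_compactness
                if node_id == self.ROOT
                else self.nodes[node_id].compactness
            )
            label = f"{node_id}:{h:.6g}" if math.isfinite(h) else node_id
            if not kids:
                return label
            return "(" + ",".join(rec(k) for k in kids) + ")" + label

        return rec(self.ROOT) + ";"


def compactness(g: CellGraph, members: np.ndarray, alpha: float) -> float:
    """Cluster compactness: mean shortest-path distance over member pairs
    divided by (ln N_c)^alpha.  Lower is more compact."""
    members = np.asarray(members)
    n_c = len(members)
    if n_c < 2:
        raise ValueError("compactness needs at least 2 members")
    spd = mean_spd(g, members)
    return spd / math.log(n_c) ** alpha


def _ego_nodes(adj: list[set], seed_node: int, n_layers: int) -> np.ndarray:
    seen = {seed_node}
    frontier = {seed_node}
    for _ in range(n_layers):
        nxt = set()
        for v in frontier:
            nxt |= adj[v]
        frontier = nxt - seen
        seen |= nxt
        if not frontier:
            break
    return np.array(sorted(seen), dtype=np.int64)


def calibrate_alpha(
    g: CellGraph,
    params: CompactnessParams | None = None,
    seed: int = 0,
) -> float:
    """Calibrate the compactness exponent from sampled ego subnetworks.

    For each of ``n_sample_nodes`` random nodes, the ``n_layers``-hop
    neighborhood gives a subnetwork with reference exponent
    alpha_o = ln(mean SPD) / ln(ln N_c); alpha* is the median alpha_o over
    the larger-than-median subnetworks, capped at ``alpha_cap``.
    """
    if params is None:
        params = CompactnessParams()
    rng = np.random.default_rng(seed)
    n = g.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    adj = g.adjacency()
    picks = rng.choice(n, size=min(params.n_sample_nodes, n), replace=n < params.n_sample_nodes)
    sizes, alphas = [], []
    for v in picks:
        nodes = _ego_nodes(adj, int(v), params.n_layers)
        n_c = len(nodes)
        if n_c < 3:
            continue
        spd = mean_spd(g, nodes)  # ego subnetworks are connected
        alphas.append(math.log(spd) / math.log(math.log(n_c)))
        sizes.append(n_c)
    if len(alphas) < 10:
        logger.warning(
            "alpha calibration: only %d valid subnetworks; falling back to alpha*=1",
            len(alphas),
        )
        return 1.0
    sizes = np.asarray(sizes)
    alphas = np.asarray(alphas)
    sel = sizes > np.median(sizes)
    if not sel.any():
        sel = np.ones(len(sizes), dtype=bool)
    return float(min(np.median(alphas[sel]), params.alpha_cap))


def _lambda_per_child(
    lu: np.ndarray, lv: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    within = lu == lv
    e_cc = np.bincount(lu[within], minlength=k)
    touch = np.bincount(lu, minlength=k) + np.bincount(lv, minlength=k)
    e_c = touch - e_cc  # edges touching c, counting within-edges once
    return e_cc, e_c


def connectivity_test(
    g_parent: CellGraph,
    labels: np.ndarray,
    swap_frac: float = 0.10,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Permutation test of intracluster connectivity lambda_c = e_cc / e_c.

    The null relabels a random ``swap_frac`` fraction of cells, each to a
    uniformly chosen *different* child label, and recomputes lambda; the
    p-value is (1 + #{lambda' >= lambda}) / (1 + n_perm).  Children touching
    no edge have undefined lambda and are reported with p = 1.
    """
    labels = np.asarray(labels, dtype=np.int64)
    k = int(labels.max()) + 1
    if k < 2:
        raise ValueError("connectivity test needs at least 2 children")
    rng = np.random.default_rng(seed)
    eu, ev = g_parent.edges_u, g_parent.edges_v
    lu, lv = labels[eu], labels[ev]
    e_cc, e_c = _lambda_per_child(lu, lv, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(e_c > 0, e_cc / np.maximum(e_c, 1), np.nan)
    n = len(labels)
    n_swap = max(1, int(math.ceil(swap_frac * n)))
    exceed = np.zeros(k, dtype=np.int64)
    for _ in range(n_perm):
        perm_labels = labels.copy()
        cells = rng.choice(n, size=n_swap, replace=False)
        # shift each selected cell to a uniformly chosen different label
        shift = rng.integers(1, k, size=n_swap)
        perm_labels[cells] = (perm_labels[cells] + shift) % k
        plu, plv = perm_labels[eu], perm_labels[ev]
        p_cc, p_c = _lambda_per_child(plu, plv, k)
        with np.errstate(invalid="ignore", divide="ignore"):
            lam_p = np.where(p_c > 0, p_cc / np.maximum(p_c, 1), np.nan)
        exceed += np.where(
            np.isnan(lam), 0, (np.nan_to_num(lam_p, nan=-1.0) >= np.nan_to_num(lam, nan=2.0))
        )
    pvals = (1 + exceed) / (1 + n_perm)
    return {
        c: (float(lam[c]) if not np.isnan(lam[c]) else float("nan"),
            float(pvals[c]) if not np.isnan(lam[c]) else 1.0)
        for c in range(k)
    }


def _safe_compactness(g: CellGraph, members: np.ndarray, alpha: float) -> float:
    try:
        return compactness(g, members, alpha)
    except ValueError:
        return math.inf  # disconnected or degenerate: maximally non-compact


def run_msc(
    expr: ExpressionMatrix,
    metric: str = "pearson_features",
    reduced: np.ndarray | None = None,
    screen_params: ScreenParams | None = None,
    grid: np.ndarray | None = None,
    min_size: int = 10,
    swap_frac: float = 0.10,
    n_perm: int = 100,
    p_threshold: float = 0.05,
    seed: int = 0,
    alpha_params: CompactnessParams | None = None,
    graph: CellGraph | None = None,
) -> ClusterHierarchy:
    """Full MSC: LEN construction, alpha* calibration, then recursive
    AdaptSplit with child acceptance by compactness improvement AND
    connectivity significance.  Node ids are assigned breadth-first
    (M1, M2, ...).  A precomputed ``graph`` skips LEN construction."""
    if grid is None:
        grid = DEFAULT_GRID
    g = graph if graph is not None else build_len(
        expr, metric=metric, params=screen_params, reduced=reduced
    )
    h = ClusterHierarchy(cell_ids=list(expr.cell_ids), graph=g)
    h.alpha_star = calibrate_alpha(g, alpha_params, seed=seed)
    all_members = np.arange(g.n_nodes, dtype=np.int64)
    h.root_compactness = _safe_compactness(g, all_members, h.alpha_star)

    counter = 0
    queue: deque = deque()
    queue.append((ClusterHierarchy.ROOT, all_members, h.root_compactness, 0))
    while queue:
        parent_id, members, v_parent, level = queue.popleft()
        if len(members) <= min_size:  # cannot hold a proper child of min_size
            continue
        sub, sub_nodes = g.subgraph(members)
        if sub.n_edges < 1:
            continue
        labels, gamma_f = adapt_split(sub, grid=grid, seed=seed)
        k = int(labels.max()) + 1
        if k < 2:
            continue
        stats = connectivity_test(
            sub, labels, swap_frac=swap_frac, n_perm=n_perm, seed=seed + counter
        )
        for c in range(k):
            part_local = np.flatnonzero(labels == c)
            if len(part_local) < min_size or len(part_local) == len(members):
                continue
            lam, p_conn = stats[c]
            if not (p_conn < p_threshold):
                continue
            v_child = _safe_compactness(sub, part_local, h.alpha_star)
            if not v_child < v_parent:
                continue
            counter += 1
            node_id = f"M{counter}"
            child_members = sub_nodes[part_local]
            h.nodes[node_id] = ClusterNode(
                id=node_id,
                members=child_members,
                parent=parent_id,
                gamma_f=gamma_f,
                compactness=v_child,
                lam=lam,
                p_conn=p_conn,
                level=level + 1,
            )
            queue.append((node_id, child_members, v_child, level + 1))
    if not h.nodes:
        logger.warning("no accepted children at the root: hierarchy is root-only")
    return h


def extract_partitions(h: ClusterHierarchy, mode: str = "first_level") -> dict:
    """Cluster sets from the hierarchy: ``first_level`` returns the disjoint
    children of the root; ``multilevel`` all non-root nodes (nested)."""
    if mode == "first_level":
        ids = [k for k, v in h.nodes.items() if v.parent == ClusterHierarchy.ROOT]
        if not ids:
            logger.warning("hierarchy has no first-level clusters")
    elif mode == "multilevel":
        ids = list(h.nodes)
    else:
        raise ValueError(f"unknown mode: {mode}")
    return {k: h.member_ids(k) for k in ids}
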