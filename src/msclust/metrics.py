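"""Evaluation metrics for (possibly overlapping) cluster sets.

Inclusion rate (IR), coverage rate (CR) and detection accuracy (DA) extend
precision, recall and the Jaccard index to overlapping clusterings: each
takes the best match per cluster and size-weights the results.  Partition
agreement (ARI, NMI, entropy-based purity/accuracy), cophenetic correlation
between a cluster hierarchy and a reference distance matrix, Jaccard layer
detection, network sparsity diagnostics and Fisher-exact sample enrichment
round out the evaluation toolbox.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, spearmanr
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from statsmodels.stats.multitest import multipletests

from .graph_core import CellGraph
from .hierarchy import ClusterHierarchy

logger = logging.getLogger(__name__)


@dataclass
class ClusterSet:
    """Named cell sets (possibly overlapping) over a universe of cell ids."""

    clusters: dict
    universe: set

    def __post_init__(self) -> None:
        for name, members in self.clusters.items():
            members = set(members)
            if not members:
                raise ValueError(f"cluster {name!r} is empty")
            if not members <= self.universe:
                raise ValueError(f"cluster {name!r} has members outside the universe")
            self.clusters[name] = members

    @classmethod
    def from_labels(cls, cell_ids, labels) -> "ClusterSet":
        clusters: dict = {}
        for cid, lab in zip(cell_ids, labels):
            clusters.setdefault(str(lab), set()).add(cid)
        return cls(clusters, set(cell_ids))


@dataclass
class NetworkStats:
    c_s: float
    cluster_ratios: dict | None = None  # label -> within/between edge ratio


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b)


def inclusion_rate(result: ClusterSet, truth: ClusterSet):
    """Size-weighted best precision per result cluster."""
    per = {
        name: max(len(c & t) / len(c) for t in truth.clusters.values())
        for name, c in result.clusters.items()
    }
    sizes = {name: len(c) for name, c in result.clusters.items()}
    total = sum(sizes.values())
    overall = sum(per[n] * sizes[n] for n in per) / total
    return overall, per


def coverage_rate(result: ClusterSet, truth: ClusterSet):
    """Size-weighted best recall per truth cluster."""
    per = {
        name: max(len(c & t) / len(t) for c in result.clusters.values())
        for name, t in truth.clusters.items()
    }
    sizes = {name: len(t) for name, t in truth.clusters.items()}
    total = sum(sizes.values())
    overall = sum(per[n] * sizes[n] for n in per) / total
    return overall, per


def detection_accuracy(result: ClusterSet, truth: ClusterSet):
    """Size-weighted best Jaccard per truth cluster."""
    per = {
        name: max(_jaccard(c, t) for c in result.clusters.values())
        for name, t in truth.clusters.items()
    }
    sizes = {name: len(t) for name, t in truth.clusters.items()}
    total = sum(sizes.values())
    overall = sum(per[n] * sizes[n] for n in per) / total
    return overall, per


def _check_partition(cs: ClusterSet) -> None:
    total = sum(len(c) for c in cs.clusters.values())
    covered = set().union(*cs.clusters.values())
    if total != len(covered) or covered != cs.universe:
        raise ValueError("cluster set is not a disjoint partition of the universe")


def _normalized_conditional_entropy(part: ClusterSet, ref: ClusterSet) -> float:
    """Size-weighted entropy of reference labels within each cluster of
    ``part``, normalized by ln(number of reference clusters); 0 = optimal."""
    k_ref = len(ref.clusters)
    if k_ref <= 1:
        return 0.0
    n = len(part.universe)
    h = 0.0
    for c in part.clusters.values():
        hc = 0.0
        for t in ref.clusters.values():
            p = len(c & t) / len(c)
            if p > 0:
                hc -= p * math.log(p)
        h += (len(c) / n) * hc
    return h / math.log(k_ref)


def partition_agreement(result: ClusterSet, truth: ClusterSet) -> dict:
    """ARI/NMI (1 = perfect) plus entropy-based purity and accuracy
    (0 = optimal): purity is the normalized entropy of truth labels within
    result clusters, accuracy the symmetric quantity over truth clusters."""
    _check_partition(result)
    _check_partition(truth)
    if result.universe != truth.universe:
        raise ValueError("partitions cover different universes")
    order = sorted(result.universe)
    res_lab = {cid: name for name, c in result.clusters.items() for cid in c}
    tru_lab = {cid: name for name, c in truth.clusters.items() for cid in c}
    a = [res_lab[c] for c in order]
    b = [tru_lab[c] for c in order]
    return {
        "ARI": float(adjusted_rand_score(b, a)),
        "NMI": float(normalized_mutual_info_score(b, a)),
        "purity": _normalized_conditional_entropy(result, truth),
        "accuracy": _normalized_conditional_entropy(truth, result),
    }


def hierarchy_cophenetic_matrix(h: ClusterHierarchy) -> np.ndarray:
    """Pairwise cophenetic distances between cells: the compactness of the
    lowest common ancestor node (root height for cells sharing no node).

    Node compactness is non-increasing with depth by construction; if a
    deeper node were less compact than its ancestor the distances are
    clipped to keep the matrix ultrametric (with a warning).
    """
    n = h.n_cells
    heights = [v.compactness for v in h.nodes.values() if math.isfinite(v.compactness)]
    top = max(heights) if heights else 1.0
    root_h = h.root_compactness
    if not math.isfinite(root_h) or root_h <= top:
        root_h = top * 1.01 + 1e-12
    D = np.full((n, n), root_h)
    # process nodes shallow -> deep so deeper (smaller) heights overwrite
    for node in sorted(h.nodes.values(), key=lambda v: v.level):
        if not math.isfinite(node.compactness):
            continue
        m = node.members
        block = D[np.ix_(m, m)]
        if (block < node.compactness).any():
            logger.warning(
                "non-monotone compactness at node %s; clipping for ultrametricity",
                node.id,
            )
        D[np.ix_(m, m)] = np.minimum(block, node.compactness)
    np.fill_diagonal(D, 0.0)
    return D


def cophenetic_correlation(h: ClusterHierarchy, truth_coph: np.ndarray) -> float:
    """Spearman correlation between the hierarchy's cophenetic distances and
    a reference cell-by-cell distance matrix (upper triangles).  Returns NaN
    with a warning when either matrix is constant."""
    truth_coph = np.asarray(truth_coph, dtype=float)
    if truth_coph.shape != (h.n_cells, h.n_cells):
        raise ValueError("truth matrix shape does not match hierarchy cells")
    D = hierarchy_cophenetic_matrix(h)
    iu = np.triu_indices(h.n_cells, k=1)
    a, b = D[iu], truth_coph[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("cophenetic correlation undefined: constant distances")
        return float("nan")
    rho, _ = spearmanr(a, b)
    return float(rho)


def layer_detection(
    result: ClusterSet,
    truth_inner: ClusterSet,
    truth_outer: ClusterSet,
    j_threshold: float = 0.8,
) -> dict:
    """Count ground-truth clusters captured in the result at each hierarchy
    layer: a truth cluster is detected iff some result cluster exceeds the
    Jaccard threshold with it."""
    out = {}
    for layer, truth in (("inner", truth_inner), ("outer", truth_outer)):
        detected = {
            name: (
                max((_jaccard(c, t) for c in result.clusters.values()), default=0.0)
                > j_threshold
            )
            for name, t in truth.clusters.items()
        }
        n_det = sum(detected.values())
        out[layer] = {
            "detected": n_det,
            "total": len(truth.clusters),
            "rate": n_det / len(truth.clusters),
            "per_cluster": detected,
        }
    return out


def network_stats(g: CellGraph, labels: np.ndarray | None = None) -> NetworkStats:
    """Sparsity c_s = |E|/|V| and, given truth labels, per-cluster
    within/between edge-count ratios (inf when a cluster has no boundary)."""
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    c_s = g.n_edges / g.n_nodes
    ratios = None
    if labels is not None:
        labels = np.asarray(labels)
        lu, lv = labels[g.edges_u], labels[g.edges_v]
        ratios = {}
        for lab in np.unique(labels):
            within = int(np.sum((lu == lab) & (lv == lab)))
            between = int(np.sum((lu == lab) ^ (lv == lab)))
            ratios[lab] = within / between if between else float("inf")
    return NetworkStats(c_s, ratios)


def fet_enrichment(
    cluster_sample_counts: pd.DataFrame,
    sample_conditions: dict,
    fdr_threshold: float = 0.05,
    sample_frac: float = 0.5,
) -> tuple[dict, pd.DataFrame]:
    """One-sided Fisher's exact test of cell-cluster over-representation per
    (cluster, sample), BH-corrected across all tests; a cluster is labeled
    with a condition when at least ``sample_frac`` of that condition's
    samples are significantly enriched."""
    counts = cluster_sample_counts
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    missing = [s for s in counts.columns if s not in sample_conditions]
    if missing:
        raise ValueError(f"samples without a condition: {missing}")
    total = counts.to_numpy().sum()
    cl_tot = counts.sum(axis=1)
    sm_tot = counts.sum(axis=0)
    rows = []
    for cl in counts.index:
        for sm in counts.columns:
            a = int(counts.loc[cl, sm])
            b = int(cl_tot[cl] - a)
            c = int(sm_tot[sm] - a)
            d = int(total - a - b - c)
            if min(a + b, a + c) == 0 or total == 0:
                p = 1.0  # degenerate margin
            else:
                _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append((cl, sm, sample_conditions[sm], a, p))
    res = pd.DataFrame(rows, columns=["cluster", "sample", "condition", "count", "p"])
    res["fdr"] = multipletests(res["p"].to_numpy(), method="fdr_bh")[1]
    res["significant"] = res["fdr"] < fdr_threshold
    cond_sizes = pd.Series(sample_conditions).value_counts()
    labels: dict = {}
    for cl, sub in res.groupby("cluster"):
        enr = []
        for cond, csub in sub.groupby("condition"):
            if csub["significant"].sum() / cond_sizes[cond] >= sample_frac:
                enr.append(cond)
        labels[cl] = sorted(enr)
    return labels, res
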