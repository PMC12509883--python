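"""Numba-compiled left-right planarity test and greedy PMFG kernel.

The per-cell neighbor embedding calls a planarity test once per candidate
edge, millions of times per dataset, so the hot path is compiled.  The
planarity routine implements the left-right (LR) criterion of Brandes'
linear-time test: orient the graph by DFS, compute lowpoints and a nesting
order, then check that the back edges admit a consistent left-right
partition by maintaining a stack of conflict pairs of edge intervals.

Only the decision is computed (no embedding).  Correctness is exercised in
the test suite against an independent planarity oracle on random graphs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NONE = np.int64(-1)


@njit(cache=True)
def _lr_planar(n, eu, ev):  # pragma: no cover - exercised via wrappers
    m = eu.shape[0]
    if m <= 8:
        return True  # K5 / K3,3 need at least 9 edges
    if n > 2 and m > 3 * n - 6:
        return False

    # --- adjacency (undirected, with edge ids) ---
    deg = np.zeros(n, dtype=np.int64)
    for i in range(m):
        deg[eu[i]] += 1
        deg[ev[i]] += 1
    off = np.zeros(n + 1, dtype=np.int64)
    for v in range(n):
        off[v + 1] = off[v] + deg[v]
    fill = off[:n].copy()
    adj_e = np.empty(2 * m, dtype=np.int64)
    adj_w = np.empty(2 * m, dtype=np.int64)
    for i in range(m):
        a = eu[i]
        b = ev[i]
        adj_e[fill[a]] = i
        adj_w[fill[a]] = b
        fill[a] += 1
        adj_e[fill[b]] = i
        adj_w[fill[b]] = a
        fill[b] += 1

    # --- phase 1: DFS orientation, lowpoints, nesting depth ---
    height = np.full(n, NONE)
    parent_edge = np.full(n, NONE)
    oriented = np.zeros(m, dtype=np.bool_)
    src = np.full(m, NONE)
    dst = np.full(m, NONE)
    lowpt = np.zeros(m, dtype=np.int64)
    lowpt2 = np.zeros(m, dtype=np.int64)
    nesting = np.zeros(m, dtype=np.int64)
    ind = np.zeros(n, dtype=np.int64)
    stack = np.empty(n + 1, dtype=np.int64)

    for root in range(n):
        if height[root] != NONE:
            continue
        height[root] = 0
        sp = 0
        stack[sp] = root
        sp += 1
        while sp > 0:
            v = stack[sp - 1]
            descended = False
            while ind[v] < deg[v]:
                pos = off[v] + ind[v]
                eid = adj_e[pos]
                w = adj_w[pos]
                ind[v] += 1
                if oriented[eid]:
                    continue
                oriented[eid] = True
                src[eid] = v
                dst[eid] = w
                lowpt[eid] = height[v]
                lowpt2[eid] = height[v]
                if height[w] == NONE:  # tree edge
                    parent_edge[w] = eid
                    height[w] = height[v] + 1
                    stack[sp] = w
                    sp += 1
                    descended = True
                    break
                # back edge: finish immediately
                lowpt[eid] = height[w]
                nd = 2 * lowpt[eid]
                if lowpt2[eid] < height[v]:
                    nd += 1
                nesting[eid] = nd
                pe = parent_edge[v]
                if pe != NONE:
                    if lowpt[eid] < lowpt[pe]:
                        lowpt2[pe] = min(lowpt[pe], lowpt2[eid])
                        lowpt[pe] = lowpt[eid]
                    elif lowpt[eid] > lowpt[pe]:
                        lowpt2[pe] = min(lowpt2[pe], lowpt[eid])
                    else:
                        lowpt2[pe] = min(lowpt2[pe], lowpt2[eid])
            if not descended:
                sp -= 1
                te = parent_edge[v]
                if te != NONE:  # finish tree edge (src -> v)
                    u = src[te]
                    nd = 2 * lowpt[te]
                    if lowpt2[te] < height[u]:
                        nd += 1
                    nesting[te] = nd
                    pe = parent_edge[u]
                    if pe != NONE:
                        if lowpt[te] < lowpt[pe]:
                            lowpt2[pe] = min(lowpt[pe], lowpt2[te])
                            lowpt[pe] = lowpt[te]
                        elif lowpt[te] > lowpt[pe]:
                            lowpt2[pe] = min(lowpt2[pe], lowpt[te])
                        else:
                            lowpt2[pe] = min(lowpt2[pe], lowpt2[te])

    # --- outgoing adjacency ordered by nesting depth ---
    outdeg = np.zeros(n, dtype=np.int64)
    for e in range(m):
        outdeg[src[e]] += 1
    off2 = np.zeros(n + 1, dtype=np.int64)
    for v in range(n):
        off2[v + 1] = off2[v] + outdeg[v]
    fill2 = off2[:n].copy()
    out_sorted = np.empty(m, dtype=np.int64)
    for e in range(m):
        out_sorted[fill2[src[e]]] = e
        fill2[src[e]] += 1
    for v in range(n):  # insertion sort per (small) segment
        lo = off2[v]
        hi = off2[v + 1]
        for i in range(lo + 1, hi):
            key = out_sorted[i]
            kd = nesting[key]
            j = i - 1
            while j >= lo and nesting[out_sorted[j]] > kd:
                out_sorted[j + 1] = out_sorted[j]
                j -= 1
            out_sorted[j + 1] = key

    # --- phase 2: LR testing with a conflict-pair stack ---
    ref = np.full(m, NONE)
    lowpt_edge = np.full(m, NONE)
    stack_bottom = np.full(m, NONE)
    # conflict pair stack: left/right intervals of edge ids
    cap = m + 2
    SLl = np.full(cap, NONE)
    SLh = np.full(cap, NONE)
    SRl = np.full(cap, NONE)
    SRh = np.full(cap, NONE)
    ssp = 0

    ind2 = np.zeros(n, dtype=np.int64)
    pending = np.full(n, NONE)

    for root in range(n):
        if parent_edge[root] != NONE or ind2[root] > 0:
            continue
        # mark isolated roots as handled
        if outdeg[root] == 0:
            ind2[root] = 0
        sp = 0
        stack[sp] = root
        sp += 1
        while sp > 0:
            v = stack[sp - 1]

            # post-process an edge whose subtree / push just completed
            if pending[v] != NONE:
                ei = pending[v]
                pending[v] = NONE
                if lowpt[ei] < height[v]:  # ei has a return edge
                    e = parent_edge[v]
                    if ei == out_sorted[off2[v]]:
                        lowpt_edge[e] = lowpt_edge[ei]
                    else:
                        # --- add constraints of ei ---
                        PLl = NONE
                        PLh = NONE
                        PRl = NONE
                        PRh = NONE
                        # merge return edges of ei into P.right
                        while True:
                            ssp -= 1
                            QLl = SLl[ssp]
                            QLh = SLh[ssp]
                            QRl = SRl[ssp]
                            QRh = SRh[ssp]
                            if QLl != NONE or QLh != NONE:
                                t = QLl
                                QLl = QRl
                                QRl = t
                                t = QLh
                                QLh = QRh
                                QRh = t
                            if QLl != NONE or QLh != NONE:
                                return False
                            if QRl != NONE and lowpt[QRl] > lowpt[e]:
                                # merge intervals
                                if PRl == NONE and PRh == NONE:
                                    PRh = QRh
                                else:
                                    ref[PRl] = QRh
                                PRl = QRl
                            elif QRl != NONE:
                                ref[QRl] = lowpt_edge[e]
                            if ssp == stack_bottom[ei]:
                                break
                        # merge conflicting return edges of earlier siblings
                        while ssp > 0:
                            TLh = SLh[ssp - 1]
                            TRh = SRh[ssp - 1]
                            confl_l = TLh != NONE and lowpt[TLh] > lowpt[ei]
                            confl_r = TRh != NONE and lowpt[TRh] > lowpt[ei]
                            if not (confl_l or confl_r):
                                break
                            ssp -= 1
                            QLl = SLl[ssp]
                            QLh = SLh[ssp]
                            QRl = SRl[ssp]
                            QRh = SRh[ssp]
                            if QRh != NONE and lowpt[QRh] > lowpt[ei]:
                                t = QLl
                                QLl = QRl
                                QRl = t
                                t = QLh
                                QLh = QRh
                                QRh = t
                            if QRh != NONE and lowpt[QRh] > lowpt[ei]:
                                return False
                            # merge interval below lowpt(ei) into P.right
                            if PRl != NONE:
                                ref[PRl] = QRh
                            if QRl != NONE:
                                PRl = QRl
                            if PLl == NONE and PLh == NONE:
                                PLh = QLh
                            else:
                                ref[PLl] = QLh
                            PLl = QLl
                        if PLl != NONE or PLh != NONE or PRl != NONE or PRh != NONE:
                            SLl[ssp] = PLl
                            SLh[ssp] = PLh
                            SRl[ssp] = PRl
                            SRh[ssp] = PRh
                            ssp += 1

            descended = False
            while ind2[v] < outdeg[v]:
                ei = out_sorted[off2[v] + ind2[v]]
                ind2[v] += 1
                w = dst[ei]
                stack_bottom[ei] = ssp
                if parent_edge[w] == ei:  # tree edge
                    pending[v] = ei
                    stack[sp] = w
                    sp += 1
                    descended = True
                    break
                # back edge
                lowpt_edge[ei] = ei
                SLl[ssp] = NONE
                SLh[ssp] = NONE
                SRl[ssp] = ei
                SRh[ssp] = ei
                ssp += 1
                pending[v] = ei
                break  # loop back to run the post-processing block
            if descended:
                continue
            if pending[v] != NONE:
                continue  # process the back edge we just pushed

            # all outgoing edges handled: leave v
            sp -= 1
            e = parent_edge[v]
            if e == NONE:
                continue
            u = src[e]
            # --- trim back edges ending at parent u ---
            while ssp > 0:
                # lowest(top)
                low = np.int64(9223372036854775807)
                if SLl[ssp - 1] != NONE:
                    low = lowpt[SLl[ssp - 1]]
                if SRl[ssp - 1] != NONE and lowpt[SRl[ssp - 1]] < low:
                    low = lowpt[SRl[ssp - 1]]
                if low != height[u]:
                    break
                ssp -= 1
            if ssp > 0:
                ssp -= 1
                PLl = SLl[ssp]
                PLh = SLh[ssp]
                PRl = SRl[ssp]
                PRh = SRh[ssp]
                # trim left interval
                while PLh != NONE and dst[PLh] == u:
                    PLh = ref[PLh]
                if PLh == NONE and PLl != NONE:
                    ref[PLl] = PRl
                    PLl = NONE
                # trim right interval
                while PRh != NONE and dst[PRh] == u:
                    PRh = ref[PRh]
                if PRh == NONE and PRl != NONE:
                    ref[PRl] = PLl
                    PRl = NONE
                SLl[ssp] = PLl
                SLh[ssp] = PLh
                SRl[ssp] = PRl
                SRh[ssp] = PRh
                ssp += 1
            if lowpt[e] < height[u] and ssp > 0:  # e has return edge
                hl = SLh[ssp - 1]
                hr = SRh[ssp - 1]
                if hl != NONE and (hr == NONE or lowpt[hl] > lowpt[hr]):
                    ref[e] = hl
                else:
                    ref[e] = hr
    return True


@njit(cache=True)
def _pmfg_kernel(n, cand_u, cand_v):  # pragma: no cover - via pmfg()
    """Greedy PMFG: insert pre-sorted candidate edges while planar, up to
    the Euler bound 3(n-2).  Returns the number of selected edges and the
    selection mask over candidates (preserving insertion order)."""
    max_edges = 3 * (n - 2)
    nc = cand_u.shape[0]
    sel_u = np.empty(max_edges, dtype=np.int64)
    sel_v = np.empty(max_edges, dtype=np.int64)
    keep = np.zeros(nc, dtype=np.bool_)
    m = 0
    for t in range(nc):
        sel_u[m] = cand_u[t]
        sel_v[m] = cand_v[t]
        m += 1
        if m > 8 and not _lr_planar(n, sel_u[:m], sel_v[:m]):
            m -= 1
            continue
        keep[t] = True
        if m >= max_edges:
            break
    return m, keep


def is_planar(n: int, eu: np.ndarray, ev: np.ndarray) -> bool:
    """Planarity of the simple graph on ``n`` nodes with the given edges."""
    return bool(
        _lr_planar(
            np.int64(n),
            np.ascontiguousarray(eu, dtype=np.int64),
            np.ascontiguousarray(ev, dtype=np.int64),
        )
    )
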