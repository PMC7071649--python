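"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: exhaustive
alignment enumeration for the profile scan, exhaustive topology search with
least-squares branch fitting for neighbor-joining, and exhaustive chain
enumeration for collinear-block finding.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def oracle_scan(seq: str, profile):
    """Enumerate every glocal alignment (free protein ends, full profile
    coverage, affine run-based gap costs) and return the best
    (score, start, gaps, column_map) under the tie order: score max,
    start min, gaps min."""
    L, N = profile.length, len(seq)
    go, ge = profile.gap_open, profile.gap_extend
    best = [None]

    def consider(score, start, gaps, cmap):
        cand = (score, start, gaps, dict(cmap))
        cur = best[0]
        if cur is None or (cand[0], -cand[1], -cand[2]) > (cur[0], -cur[1], -cur[2]):
            best[0] = cand

    def rec(i, j, state, score, start, gaps, cmap):
        if j == L:
            if state != "I":
                consider(score, start if start is not None else i + 1, gaps, cmap)
            return
        if i < N:
            s = profile.score(j + 1, seq[i])
            cmap[j + 1] = i + 1
            rec(i + 1, j + 1, "M", score + s,
                start if start is not None else i + 1, gaps, cmap)
            del cmap[j + 1]
        pen = ge if state == "D" else go
        cmap[j + 1] = None
        rec(i, j + 1, "D", score - pen, start, gaps + 1, cmap)
        del cmap[j + 1]
        if j >= 1 and i < N:
            pen = ge if state == "I" else go
            rec(i + 1, j, "I", score - pen, start, gaps + 1, cmap)

    for i0 in range(N + 1):
        rec(i0, 0, "S", 0.0, None, 0, {})
    return best[0]


def all_unrooted_topologies(taxa: list[str]) -> list[nx.Graph]:
    """All unrooted binary topologies over the taxa (3 -> 1, 6 -> 105)."""
    base = nx.Graph()
    base.add_edges_from([("_c0", taxa[0]), ("_c0", taxa[1]), ("_c0", taxa[2])])
    trees = [base]
    for k, taxon in enumerate(taxa[3:], start=1):
        nxt = []
        for t in trees:
            for u, v in list(t.edges()):
                g = t.copy()
                g.remove_edge(u, v)
                new = f"_n{k}_{u}_{v}"
                g.add_edges_from([(u, new), (v, new), (new, taxon)])
                nxt.append(g)
        trees = nxt
    return trees


def tree_bipartitions(g: nx.Graph, taxa: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions of a leaf-labeled tree graph."""
    out = set()
    full = frozenset(taxa)
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(h, u) if x in full)
        if 1 < len(side) < len(taxa) - 1:
            out.add(min(side, full - side, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def ls_fit_sse(g: nx.Graph, taxa: list[str], d: np.ndarray) -> float:
    """Least-squares fit of branch lengths to the distance matrix; returns
    the residual sum of squares."""
    edges = list(g.edges())
    rows, y = [], []
    for i, j in itertools.combinations(range(len(taxa)), 2):
        path = nx.shortest_path(g, taxa[i], taxa[j])
        on_path = {frozenset(e) for e in zip(path, path[1:])}
        rows.append([1.0 if frozenset(e) in on_path else 0.0 for e in edges])
        y.append(d[i, j])
    A = np.array(rows)
    x, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
    resid = A @ x - np.array(y)
    return float(resid @ resid)


def best_ls_topology(taxa: list[str], d: np.ndarray) -> set[frozenset]:
    """Bipartitions of the topology minimising least-squares SSE."""
    best_sse, best_bip = np.inf, None
    for g in all_unrooted_topologies(taxa):
        sse = ls_fit_sse(g, taxa, d)
        if sse < best_sse - 1e-12:
            best_sse, best_bip = sse, tree_bipartitions(g, taxa)
    return best_bip


def random_additive_matrix(taxa: list[str], rng: np.random.Generator):
    """A random binary tree over the taxa and its additive path-distance
    matrix; returns (distance matrix, true bipartitions)."""
    g = nx.Graph()
    pool = list(taxa)
    cnt = 0
    while len(pool) > 2:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[j], pool[i]
        cnt += 1
        u = f"_i{cnt}"
        g.add_edge(a, u, w=float(rng.uniform(0.05, 0.5)))
        g.add_edge(b, u, w=float(rng.uniform(0.05, 0.5)))
        pool = [p for p in pool if p not in (a, b)] + [u]
    g.add_edge(pool[0], pool[1], w=float(rng.uniform(0.05, 0.5)))
    n = len(taxa)
    d = np.zeros((n, n))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="w"))
    for i in range(n):
        for j in range(n):
            d[i, j] = lengths[taxa[i]][taxa[j]]
    return d, tree_bipartitions(g, taxa)


def enumerate_chains(anchors, min_pairs: int, max_gap: int):
    """All maximal-length monotone chains over anchor pairs
    (rank_a, rank_b), both orientations; returns the maximum chain length
    (0 if none reaches min_pairs)."""
    n = len(anchors)
    best = 0
    for sign in (1, -1):
        # a chain is determined by its anchor subset taken in rank_a order
        for size in range(n, min_pairs - 1, -1):
            if size <= best:
                break
            for subset in itertools.combinations(range(n), size):
                chain = sorted(subset, key=lambda k: anchors[k][0])
                ok = True
                for x, y in zip(chain, chain[1:]):
                    da = anchors[y][0] - anchors[x][0]
                    db = (anchors[y][1] - anchors[x][1]) * sign
                    if da <= 0 or db <= 0 or da - 1 > max_gap or db - 1 > max_gap:
                        ok = False
                        break
                if ok:
                    best = max(best, size)
                    break
    return best
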