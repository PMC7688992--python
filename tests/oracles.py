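"""Independent brute-force oracles used to check the package's routines.

Everything here is deliberately naive — exhaustive enumeration, hand-rolled
agglomeration, exact expectations — and shares no code path with the
implementation under test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, factorial

import networkx as nx
import numpy as np


def fisher_two_tailed_exact(k: int, K: int, n: int, N: int) -> float:
    """Two-tailed Fisher P by exact rational enumeration of all 2x2 tables
    with the observed margins (point-probability rule)."""
    def point(kk: int) -> Fraction:
        return Fraction(comb(K, kk) * comb(N - K, n - kk), comb(N, n))

    observed = point(k)
    total = Fraction(0)
    for kk in range(max(0, n + K - N), min(n, K) + 1):
        if point(kk) <= observed:
            total += point(kk)
    return float(total)


def upgma_merge_heights(points: np.ndarray) -> list[float]:
    """Hand-coded UPGMA on Euclidean distances; returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(points))}
    dist = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i in range(len(points))
        for j in range(i + 1, len(points))
    }
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters.pop(a) + clusters.pop(b)
        new_dist = {}
        for pair, d in dist.items():
            if a in pair or b in pair:
                continue
            new_dist[pair] = d
        for c, members in clusters.items():
            # average of all original point-pair distances (UPGMA definition)
            d = float(
                np.mean(
                    [
                        np.linalg.norm(points[x] - points[y])
                        for x in merged
                        for y in members
                    ]
                )
            )
            new_dist[(min(c, next_id), max(c, next_id))] = d
        clusters[next_id] = merged
        dist = new_dist
        next_id += 1
    return sorted(heights)


def mcc_bruteforce(graph: nx.Graph) -> dict:
    """Maximal-clique centrality by exhaustive subset enumeration."""
    nodes = list(graph.nodes)
    cliques = []
    for r in range(2, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(graph.has_edge(u, v) for u, v in itertools.combinations(subset, 2)):
                cliques.append(set(subset))
    maximal = [
        c for c in cliques if not any(c < other for other in cliques)
    ]
    out = {v: 0.0 for v in nodes}
    for c in maximal:
        for v in c:
            out[v] += factorial(len(c) - 1)
    return out


def _bfs_dist(graph: nx.Graph, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in graph.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def closeness_bruteforce(graph: nx.Graph) -> dict:
    return {
        v: sum(1.0 / d for w, d in _bfs_dist(graph, v).items() if w != v)
        for v in graph.nodes
    }


def radiality_bruteforce(graph: nx.Graph) -> dict:
    out = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        all_dist = {v: _bfs_dist(sub, v) for v in comp}
        diameter = max(max(d.values()) for d in all_dist.values())
        for v in comp:
            out[v] = sum(
                diameter + 1 - d for w, d in all_dist[v].items() if w != v
            ) / (len(comp) - 1)
    return out


def mnc_bruteforce(graph: nx.Graph) -> dict:
    out = {}
    for v in graph.nodes:
        nbrs = set(graph.neighbors(v))
        best = 0
        seen = set()
        for start in nbrs:
            if start in seen:
                continue
            comp = {start}
            frontier = [start]
            while frontier:
                u = frontier.pop()
                for w in graph.neighbors(u):
                    if w in nbrs and w not in comp:
                        comp.add(w)
                        frontier.append(w)
            seen |= comp
            best = max(best, len(comp))
        out[v] = float(best)
    return out


def epc_exact(graph: nx.Graph, keep_prob: float = 0.5) -> dict:
    """Exact expected percolated-component size over all 2^E edge states."""
    edges = list(graph.edges)
    nodes = list(graph.nodes)
    totals = {v: 0.0 for v in nodes}
    for mask in range(2 ** len(edges)):
        kept = [e for i, e in enumerate(edges) if mask >> i & 1]
        prob = keep_prob ** len(kept) * (1 - keep_prob) ** (len(edges) - len(kept))
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(kept)
        for comp in nx.connected_components(g):
            for v in comp:
                totals[v] += prob * len(comp)
    return totals
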