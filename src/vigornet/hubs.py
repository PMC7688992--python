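"""Six node-centrality measures and intersection-based hub calling.

Hub genes are defined procedurally: rank every node by each of six
measures — degree, maximum neighborhood component (MNC), maximal clique
centrality (MCC), edge percolated component (EPC), closeness and
radiality — take the top 10 of each, and call the nodes common to all six
lists the hubs.

Definitions (on an undirected simple graph):

* degree(v): number of neighbours.
* mnc(v): size of the largest connected component of the subgraph induced
  by v's neighbours.
* mcc(v): sum of (|C| - 1)! over maximal cliques C containing v; an
  isolated node scores 0, and a node whose neighbourhood is edgeless
  scores exactly its degree (each incident edge is a maximal 2-clique).
* closeness(v): harmonic closeness, sum of 1/d(v, w) over all other
  nodes, unreachable nodes contributing 0.
* radiality(v): sum over w in v's component of (D + 1 - d(v, w)) divided
  by (n_c - 1), where D is the component diameter and n_c its size;
  0 for an isolated node.  Computing per component keeps the score finite
  on disconnected graphs.
* epc(v): mean, over Monte-Carlo replicates in which every edge is kept
  independently with probability ``keep_prob``, of the size of the
  percolated component containing v.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import factorial
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError

METHODS = ("degree", "mnc", "mcc", "epc", "closeness", "radiality")


@dataclass(frozen=True)
class EpcParams:
    """Edge-percolation Monte-Carlo settings."""

    replicates: int = 1000
    keep_prob: float = 0.5
    seed: int = 0


def _check_graph(graph: nx.Graph) -> None:
    if graph.is_directed() or graph.is_multigraph():
        raise InputError(
            "centrality requires an undirected simple graph; "
            "project the network first (see integration.simple_projection)"
        )
    if graph.number_of_nodes() == 0:
        raise InputError("graph has no nodes")


def degree_centrality(graph: nx.Graph) -> dict[str, float]:
    return {v: float(d) for v, d in graph.degree()}


def mnc(graph: nx.Graph) -> dict[str, float]:
    out = {}
    for v in graph.nodes:
        nbrs = list(graph.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        sub = graph.subgraph(nbrs)
        out[v] = float(max(len(c) for c in nx.connected_components(sub)))
    return out


def mcc(graph: nx.Graph) -> dict[str, float]:
    out = {v: 0.0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:  # isolated nodes score 0
            continue
        w = float(factorial(len(clique) - 1))
        for v in clique:
            out[v] += w
    return out


def closeness(graph: nx.Graph) -> dict[str, float]:
    """Harmonic closeness: unreachable pairs contribute 0."""
    return {v: float(s) for v, s in nx.harmonic_centrality(graph).items()}


def radiality(graph: nx.Graph) -> dict[str, float]:
    out = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        n_c = len(comp)
        if n_c == 1:
            out.update({v: 0.0 for v in comp})
            continue
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diameter = max(max(d.values()) for d in dist.values())
        for v in comp:
            total = sum(diameter + 1 - d for w, d in dist[v].items() if w != v)
            out[v] = total / (n_c - 1)
    return out


def epc(graph: nx.Graph, params: EpcParams | None = None) -> dict[str, float]:
    """Monte-Carlo edge-percolated component size, seeded and reproducible."""
    params = params or EpcParams()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(7,))
    )
    nodes = list(graph.nodes)
    edges = list(graph.edges)
    totals = {v: 0.0 for v in nodes}
    for _ in range(params.replicates):
        keep = rng.random(len(edges)) < params.keep_prob
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(e for e, k in zip(edges, keep) if k)
        for comp in nx.connected_components(g):
            size = float(len(comp))
            for v in comp:
                totals[v] += size
    return {v: t / params.replicates for v, t in totals.items()}


def compute_centrality(
    graph: nx.Graph, method: str, epc_params: EpcParams | None = None
) -> dict[str, float]:
    """Dispatch one of the six measures; see module docstring for definitions."""
    _check_graph(graph)
    if method == "degree":
        return degree_centrality(graph)
    if method == "mnc":
        return mnc(graph)
    if method == "mcc":
        return mcc(graph)
    if method == "epc":
        return epc(graph, epc_params)
    if method == "closeness":
        return closeness(graph)
    if method == "radiality":
        return radiality(graph)
    raise InputError(f"unknown centrality method {method!r}; expected one of {METHODS}")


def centrality_table(
    graph: nx.Graph, epc_params: EpcParams | None = None
) -> pd.DataFrame:
    """All six scores for every node (columns in :data:`METHODS` order)."""
    _check_graph(graph)
    cols = {m: compute_centrality(graph, m, epc_params) for m in METHODS}
    table = pd.DataFrame(cols, columns=list(METHODS))
    table.index.name = "node"
    return table.sort_index()


def top_k(scores: Mapping[str, float], k: int = 10) -> list[str]:
    """Top-k node ids by descending score, ties by ascending node id."""
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    ranked = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    return [v for v, _ in ranked[:k]]


@dataclass(frozen=True)
class HubCallResult:
    """Six ranked top-k lists, their intersection, and per-hub rank-1 counts."""

    top_lists: dict[str, list[str]]
    hubs: list[str]
    first_rank_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "top_lists": self.top_lists,
            "hubs": self.hubs,
            "first_rank_counts": self.first_rank_counts,
        }


def call_hubs(top_lists: Mapping[str, Sequence[str]] | Sequence[Sequence[str]]) -> HubCallResult:
    """Intersect six top-k lists into the hub set.

    Accepts either a mapping method -> ranked list or a plain sequence of
    six ranked lists.  Hubs are the nodes present in every list, reported
    in sorted order; ``first_rank_counts`` says in how many lists each hub
    holds rank 1.
    """
    if isinstance(top_lists, Mapping):
        lists = {str(k): list(v) for k, v in top_lists.items()}
    else:
        lists = {f"method_{i + 1}": list(v) for i, v in enumerate(top_lists)}
    if len(lists) != 6:
        raise InputError(f"expected exactly six ranked lists, got {len(lists)}")
    sets = [set(v) for v in lists.values()]
    hubs = sorted(set.intersection(*sets)) if sets else []
    first = {h: sum(1 for v in lists.values() if v and v[0] == h) for h in hubs}
    return HubCallResult(top_lists=lists, hubs=hubs, first_rank_counts=first)


def rank_and_call(
    graph: nx.Graph, k: int = 10, epc_params: EpcParams | None = None
) -> tuple[pd.DataFrame, HubCallResult]:
    """Full hub-calling procedure: score, rank and intersect."""
    table = centrality_table(graph, epc_params)
    tops = {m: top_k(table[m].to_dict(), k) for m in METHODS}
    return table, call_hubs(tops)


def write_hub_results(
    table: pd.DataFrame, result: HubCallResult, outdir: str | Path
) -> None:
    """Write centrality.tsv, topk.json and hubs.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "centrality.tsv", sep="\t", float_format="%.6g")
    (outdir / "topk.json").write_text(json.dumps(result.top_lists, indent=2) + "\n")
    (outdir / "hubs.json").write_text(
        json.dumps(
            {"hubs": result.hubs, "first_rank_counts": result.first_rank_counts},
            indent=2,
        )
        + "\n"
    )
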