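"""Merge consensus, protein-interaction and miRNA-target edges.

The protein-interaction lookup is restricted by a node-selection rule: the
differential-protein genes (P), the miRNA target genes (T), and those
differential transcripts that share a consensus edge (in either direction)
with a member of P or T.  Interaction edges are filtered at a combined
score of at least 400 ("medium confidence" on the 0-1000 scale) and
restricted to the selected nodes.  The three edge sources are then merged
into one node-attributed multigraph; duplicated pairs from different
sources stay as distinct edges tagged by source, while node degrees are
computed on the undirected simple projection (each neighbour counted
once).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import InputError
from .grn import ConsensusNetwork

#: Functional categories annotated on network nodes.
FUNCTIONAL_CATEGORIES = (
    "stress response",
    "protein processing in ER",
    "embryo development",
    "serine-type endopeptidase inhibitor",
    "energy metabolism",
    "other",
)

MEDIUM_CONFIDENCE = 400


def select_ppi_input(
    consensus: ConsensusNetwork,
    dep_gene_set: Iterable[str],
    mirna_target_set: Iterable[str],
    degs: Iterable[str],
) -> set[str]:
    """Nodes eligible for the protein-interaction lookup.

    P ∪ T plus every differential transcript adjacent (either direction)
    to a member of P ∪ T in the consensus network.
    """
    P, T = set(dep_gene_set), set(mirna_target_set)
    seed = P | T
    degs = set(degs)
    linked = set()
    for f, t in consensus.edge_set():
        if f in seed and t in degs:
            linked.add(t)
        if t in seed and f in degs:
            linked.add(f)
    return seed | linked


def filter_ppi(
    edges: pd.DataFrame,
    node_set: Iterable[str] | None = None,
    min_score: int = MEDIUM_CONFIDENCE,
) -> pd.DataFrame:
    """Keep interaction edges with combined score >= ``min_score`` (inclusive),
    both endpoints inside ``node_set`` when one is given."""
    required = {"node_a", "node_b", "combined_score"}
    if not required <= set(edges.columns):
        raise InputError(f"interaction table needs columns {sorted(required)}")
    scores = edges["combined_score"]
    if len(edges) and ((scores < 0) | (scores > 1000)).any():
        raise InputError("combined_score outside [0, 1000]")
    out = edges[scores >= min_score]
    if node_set is not None:
        nodes = set(node_set)
        out = out[out["node_a"].isin(nodes) & out["node_b"].isin(nodes)]
    return out.reset_index(drop=True)


def integrate(
    consensus: ConsensusNetwork,
    ppi: pd.DataFrame,
    mirna_targets: Iterable[str],
    deg_set: Iterable[str] = (),
    dep_gene_set: Iterable[str] = (),
    category_map: Mapping[str, str] | None = None,
    mirna_id: str = "miRNA",
) -> nx.MultiGraph:
    """Merge the three edge sources into one attributed network.

    Consensus edges carry ``source="consensus"`` and their sign; filtered
    interaction edges carry ``source="ppi"`` and their score; one directed
    miRNA -> target edge per target gene carries ``source="mirna_target"``.
    Node attributes: ``role`` (mirna_target > dep > deg > factor > other,
    first match wins), ``functional_category`` and ``degree`` (computed on
    the simple undirected projection).
    """
    category_map = dict(category_map or {})
    for gene, cat in category_map.items():
        if cat not in FUNCTIONAL_CATEGORIES:
            raise InputError(
                f"unknown functional category {cat!r} for {gene}; "
                f"expected one of {FUNCTIONAL_CATEGORIES}"
            )
    mirna_targets = set(mirna_targets)
    deg_set, dep_gene_set = set(deg_set), set(dep_gene_set)

    g = nx.MultiGraph()
    for (f, t), rec in sorted(consensus.edges.items()):
        g.add_edge(f, t, source="consensus", sign=rec["sign"], count=rec["count"],
                   directed=True, factor=f)
    for row in ppi.itertuples():
        g.add_edge(row.node_a, row.node_b, source="ppi",
                   score=int(row.combined_score), directed=False)
    for t in sorted(mirna_targets):
        g.add_edge(mirna_id, t, source="mirna_target", directed=True, factor=mirna_id)

    factors = {f for (f, _t) in consensus.edge_set()}
    for node in g.nodes:
        if node == mirna_id:
            role = "mirna"
        elif node in mirna_targets:
            role = "mirna_target"
        elif node in dep_gene_set:
            role = "dep"
        elif node in deg_set:
            role = "deg"
        elif node in factors:
            role = "factor"
        else:
            role = "other"
        g.nodes[node]["role"] = role
        g.nodes[node]["functional_category"] = category_map.get(node, "none")

    simple = simple_projection(g)
    for node in g.nodes:
        g.nodes[node]["degree"] = simple.degree(node)
    return g


def simple_projection(g: nx.MultiGraph) -> nx.Graph:
    """Undirected simple graph: parallel edges collapsed, directions dropped.

    This is the graph the centrality stage operates on.
    """
    simple = nx.Graph()
    simple.add_nodes_from(g.nodes(data=True))
    for u, v in g.edges():
        if u != v:
            simple.add_edge(u, v)
    return simple


def write_integrated(g: nx.MultiGraph, outdir: str | Path) -> None:
    """Write integrated.graphml and integrated_edges.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, outdir / "integrated.graphml")
    rows = [
        {
            "node_a": u,
            "node_b": v,
            "source": d.get("source"),
            "directed": d.get("directed", False),
            "score": d.get("score", ""),
            "sign": d.get("sign", ""),
            "count": d.get("count", ""),
        }
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["node_a", "node_b", "source", "directed", "score", "sign", "count"]
    ).to_csv(outdir / "integrated_edges.tsv", sep="\t", index=False)
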