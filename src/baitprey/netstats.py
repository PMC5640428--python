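"""Summary statistics on protein-protein interaction graphs.

Graphs are undirected and simple: self-loops are rejected and multi-edges
from different provenance databases collapse to a single edge. The
clustering coefficient is the mean of local (Watts-Strogatz) coefficients;
nodes of degree < 2 contribute 0 and are included in the mean by default, a
convention that must be stated because graph tools differ on it.
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx

from .model import ValidationError


def build_graph(
    edges: Iterable[tuple[str, str, Optional[str]]],
    extra_nodes: Iterable[str] = (),
) -> nx.Graph:
    """Build an undirected simple graph from (node_a, node_b, provenance)
    triples. Parallel edges merge, accumulating provenance labels."""
    g = nx.Graph()
    for a, b, prov in edges:
        if a == b:
            raise ValidationError(f"self-loop on node {a!r}")
        if g.has_edge(a, b):
            if prov:
                g.edges[a, b].setdefault("provenance", set()).add(prov)
        else:
            g.add_edge(a, b, provenance={prov} if prov else set())
    g.add_nodes_from(extra_nodes)
    return g


def local_clustering(graph: nx.Graph, node: str) -> float:
    """2 T(v) / (k(v) (k(v)-1)), and 0 for degree < 2."""
    if node not in graph:
        raise ValidationError(f"node {node!r} not in graph")
    return nx.clustering(graph, node)


def average_clustering(graph: nx.Graph, count_low_degree: bool = True) -> float:
    """Mean local clustering over nodes; with ``count_low_degree=False``,
    degree-<2 nodes are excluded from the mean instead of contributing 0."""
    if graph.number_of_nodes() == 0:
        raise ValidationError("graph is empty")
    if count_low_degree:
        return nx.average_clustering(graph, count_zeros=True)
    eligible = [n for n in graph if graph.degree(n) >= 2]
    if not eligible:
        raise ValidationError("no node of degree >= 2")
    cc = nx.clustering(graph, eligible)
    return sum(cc.values()) / len(eligible)


def average_neighbors(graph: nx.Graph) -> float:
    """Mean node degree, 2 |E| / |V|."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValidationError("graph is empty")
    return 2.0 * graph.number_of_edges() / n


def subnetwork_extract(graph: nx.Graph, node_subset: Iterable[str]) -> nx.Graph:
    """Induced subgraph on ``node_subset`` (must be a subset of the nodes)."""
    subset = set(node_subset)
    missing = subset - set(graph.nodes)
    if missing:
        raise ValidationError(f"nodes not in graph: {sorted(missing)}")
    return graph.subgraph(subset).copy()
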