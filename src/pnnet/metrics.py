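"""Centrality indices, edge-betweenness communities, and graph layout.

All three centrality indices are computed on the *unweighted* sparsified
graph: degree is the number of incident edges; closeness is the
reciprocal of the sum of unweighted shortest-path distances to all other
nodes; betweenness is Brandes' shortest-path betweenness with each
unordered node pair counted once and shortest-path ties split
fractionally.  Community detection is Girvan-Newman edge-betweenness
removal with the dendrogram cut chosen by Newman-Girvan modularity on
the original unweighted graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "centrality_indices",
    "CommunityPartition",
    "girvan_newman_communities",
    "fruchterman_reingold_layout",
]


def centrality_indices(graph: nx.Graph, strict: bool = False) -> pd.DataFrame:
    """Degree, betweenness and closeness per node, on the unweighted graph.

    Returns a DataFrame indexed by node with columns
    ``degree`` (int), ``betweenness`` (float, unnormalized Brandes counts)
    and ``closeness`` (float, ``1 / sum_j d(v, j)``).

    For a disconnected graph, closeness is computed within each connected
    component (with a warning); ``strict=True`` rejects disconnected
    graphs instead.  An isolated node gets closeness 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    connected = nx.is_connected(graph)
    if not connected:
        if strict:
            raise ValueError("graph is disconnected (strict mode)")
        warnings.warn(
            "graph is disconnected; closeness computed per connected component",
            stacklevel=2,
        )
    btw = nx.betweenness_centrality(graph, normalized=False)
    rows = {}
    for v in graph.nodes:
        dists = nx.single_source_shortest_path_length(graph, v)
        total = sum(dists.values())
        rows[v] = {
            "degree": graph.degree(v),
            "betweenness": btw[v],
            "closeness": 1.0 / total if total > 0 else 0.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "node"
    out["degree"] = out["degree"].astype(int)
    return out.loc[list(graph.nodes)]


@dataclass
class CommunityPartition:
    """Result of edge-betweenness community detection.

    ``communities`` is the modularity-best partition (each community a
    frozenset of nodes); ``removal_order`` the sequence of removed edges;
    ``modularity_by_cut`` maps community count -> modularity of that
    dendrogram cut (community count 1 is the trivial single cluster,
    modularity 0).
    """

    communities: tuple[frozenset, ...]
    removal_order: tuple[tuple, ...]
    modularity_by_cut: dict[int, float]

    @property
    def modularity(self) -> float:
        return self.modularity_by_cut[len(self.communities)]

    def membership(self) -> dict:
        return {v: i for i, comm in enumerate(self.communities) for v in comm}


def _most_central_edge(graph: nx.Graph):
    # max edge betweenness, ties broken by lexicographic edge label order
    eb = nx.edge_betweenness_centrality(graph, normalized=False)
    return min(eb, key=lambda e: (-eb[e], tuple(sorted(map(str, e)))))


def girvan_newman_communities(graph: nx.Graph) -> CommunityPartition:
    """Girvan-Newman clustering with the modularity-maximizing cut.

    Iteratively removes the edge with the highest (unweighted)
    edge betweenness, recomputing after every removal; among all
    dendrogram cuts (including the trivial one-community cut) the
    partition maximizing unweighted Newman-Girvan modularity on the
    *original* graph is returned.  Ties in edge betweenness are broken
    by lexicographic edge order, making the removal sequence
    deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    work = nx.Graph(graph.edges())
    work.add_nodes_from(graph.nodes)

    trivial = (frozenset(graph.nodes),)
    cuts: dict[int, tuple[frozenset, ...]] = {1: trivial}
    removal: list[tuple] = []
    if graph.number_of_edges() > 0:
        while work.number_of_edges() > 0:
            edge = _most_central_edge(work)
            removal.append(tuple(sorted(map(str, edge))))
            work.remove_edge(*edge)
            comms = tuple(frozenset(c) for c in nx.connected_components(work))
            cuts.setdefault(len(comms), comms)
    mod = {
        k: (nx.community.modularity(graph, comms, weight=None) if k > 1 else 0.0)
        for k, comms in cuts.items()
    }
    best_k = max(mod, key=lambda k: (mod[k], -k))
    best = tuple(sorted(cuts[best_k], key=lambda c: sorted(map(str, c))))
    return CommunityPartition(
        communities=best,
        removal_order=tuple(removal),
        modularity_by_cut=mod,
    )


def fruchterman_reingold_layout(
    graph: nx.Graph, seed: int = 0, iterations: int = 50
) -> dict:
    """Seeded Fruchterman-Reingold force-directed node coordinates."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_nodes() == 1:
        return {next(iter(graph.nodes)): (0.0, 0.0)}
    pos = nx.spring_layout(graph, seed=seed, iterations=iterations)
    return {v: (float(x), float(y)) for v, (x, y) in pos.items()}
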