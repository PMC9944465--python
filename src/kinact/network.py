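"""PPI network construction, centralities, and the hub-bottleneck rule.

The network is the subgraph of a confidence-filtered protein-protein
interaction edge list induced on the study's protein identifiers; proteins
with no retained interaction stay in the graph as isolated nodes.  Node
importance is scored four ways — degree, shortest-path betweenness
(normalized within each connected component), closeness (component-local,
normalized) and Shimbel stress (the raw count of shortest paths passing
through the node, endpoints excluded).  *Hubs* are the top fraction (default
10%, ceiling) of main-component nodes by degree, *bottlenecks* the top-k
(default 10) by betweenness, and *hub-bottlenecks* their intersection.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import EdgeList

__all__ = [
    "PPINetwork",
    "HubBottleneckResult",
    "build_ppi_network",
    "node_centralities",
    "stress_centrality",
    "identify_hub_bottlenecks",
]


@dataclass
class PPINetwork:
    graph: nx.Graph
    components: list[frozenset[str]]  # sorted largest first
    main_component: frozenset[str]

    @property
    def isolated_nodes(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.degree(n) == 0)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class HubBottleneckResult:
    hubs: list[str]
    bottlenecks: list[str]
    hub_bottlenecks: list[str]
    parameters: tuple[float, int]


def build_ppi_network(edges: EdgeList, restrict_to: set[str] | None = None) -> PPINetwork:
    """Induced subgraph on ``restrict_to``; identifiers absent from the edge
    list are retained as isolated nodes (the study's networks report them)."""
    G = nx.Graph()
    if restrict_to is not None:
        if not restrict_to:
            raise ValueError("restrict_to must be non-empty")
        G.add_nodes_from(sorted(restrict_to))
        for a, b, conf, action in edges.records:
            if a in restrict_to and b in restrict_to:
                G.add_edge(a, b, confidence=conf, action_type=action)
    else:
        for a, b, conf, action in edges.records:
            G.add_edge(a, b, confidence=conf, action_type=action)
    if G.number_of_nodes() == 0:
        raise ValueError("induced network is empty")
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(G)),
        key=lambda c: (-len(c), min(c)),
    )
    return PPINetwork(graph=G, components=comps, main_component=comps[0])


def _bfs_sigma(adj: dict, source) -> tuple[dict, dict]:
    """Distances and shortest-path counts from one source (unweighted BFS)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def stress_centrality(G: nx.Graph) -> dict:
    """Shimbel stress: number of shortest paths through each node.

    For every unordered pair (s, t) and interior node v, the pair contributes
    sigma(s, v) * sigma(v, t) paths when d(s, v) + d(v, t) = d(s, t).
    """
    nodes = list(G.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = {v: list(G.neighbors(v)) for v in nodes}
    D = np.full((n, n), np.inf)
    S = np.zeros((n, n))
    for v in nodes:
        dist, sigma = _bfs_sigma(adj, v)
        i = index[v]
        for w, d in dist.items():
            D[i, index[w]] = d
            S[i, index[w]] = sigma[w]
    stress = {}
    for v in nodes:
        i = index[v]
        on_path = D[:, i][:, None] + D[i, :][None, :] == D
        contrib = S[:, i][:, None] * S[i, :][None, :]
        contrib = np.where(on_path & np.isfinite(D), contrib, 0.0)
        contrib[i, :] = 0.0
        contrib[:, i] = 0.0
        np.fill_diagonal(contrib, 0.0)
        stress[v] = int(round(contrib.sum() / 2.0))
    return stress


def node_centralities(network: PPINetwork) -> pd.DataFrame:
    """Degree, betweenness, closeness and stress per node.

    Betweenness and closeness are computed and normalized within each
    connected component (component size n: betweenness scaled by
    2/((n-1)(n-2)), closeness = (n-1)/sum of distances), matching how the
    standard network-analyzer tools report them; isolated nodes score zero.
    """
    G = network.graph
    rows = {n: {"degree": G.degree(n), "betweenness": 0.0, "closeness": 0.0} for n in G.nodes}
    for comp in network.components:
        sub = G.subgraph(comp)
        if len(comp) >= 3:
            for n, b in nx.betweenness_centrality(sub, normalized=True).items():
                rows[n]["betweenness"] = b
        if len(comp) >= 2:
            for n, c in nx.closeness_centrality(sub, wf_improved=False).items():
                rows[n]["closeness"] = c
    stress = stress_centrality(G)
    out = pd.DataFrame(
        [
            {
                "node": n,
                "degree": rows[n]["degree"],
                "betweenness": rows[n]["betweenness"],
                "closeness": rows[n]["closeness"],
                "stress": stress[n],
            }
            for n in sorted(G.nodes)
        ]
    )
    return out


def identify_hub_bottlenecks(
    records: pd.DataFrame,
    network: PPINetwork | None = None,
    hub_fraction: float = 0.10,
    bottleneck_count: int = 10,
) -> HubBottleneckResult:
    """Top-degree hubs, top-betweenness bottlenecks, and their intersection.

    The hub count is ceil(hub_fraction x main-component size) when the
    network is given (isolates are excluded from the ranking pool), otherwise
    ceil(hub_fraction x number of records).  Ties break deterministically:
    hubs by (degree, betweenness, id), bottlenecks by (betweenness, degree,
    id).
    """
    if len(records) == 0:
        raise ValueError("no centrality records")
    pool = records
    if network is not None:
        pool = records[records["node"].isin(network.main_component)]
        n_pool = len(network.main_component)
    else:
        n_pool = len(records)
    n_hubs = math.ceil(hub_fraction * n_pool)
    if bottleneck_count > len(pool):
        warnings.warn(
            f"bottleneck_count {bottleneck_count} exceeds {len(pool)} nodes; clipping",
            stacklevel=2,
        )
        bottleneck_count = len(pool)
    hub_sorted = pool.sort_values(
        ["degree", "betweenness", "node"], ascending=[False, False, True], kind="mergesort"
    )
    btw_sorted = pool.sort_values(
        ["betweenness", "degree", "node"], ascending=[False, False, True], kind="mergesort"
    )
    hubs = list(hub_sorted["node"].head(n_hubs))
    bottlenecks = list(btw_sorted["node"].head(bottleneck_count))
    common = set(hubs) & set(bottlenecks)
    hub_bottlenecks = [n for n in hubs if n in common]
    return HubBottleneckResult(
        hubs=hubs,
        bottlenecks=bottlenecks,
        hub_bottlenecks=hub_bottlenecks,
        parameters=(hub_fraction, bottleneck_count),
    )
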