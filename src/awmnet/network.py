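"""Gene co-association network assembly and topology statistics.

The network is undirected: nodes are genes (isolated nodes are retained and
counted), edges are PCIT-significant correlations weighted by r, and
regulator flags come from a case-insensitive match against the census.
Topology statistics are computed directly from adjacency sets (not through
a graph library) so that tests can cross-check them against an independent
implementation: mean local clustering with degree<2 nodes contributing 0,
and the average shortest-path length over connected distinct pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class CoAssocNetwork:
    """Undirected weighted gene network with regulator flags."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def regulators(self) -> list:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("is_regulator", False)
        )

    def neighbors(self, node) -> set:
        return set(self.graph.neighbors(node))

    def isolated_nodes(self) -> list:
        return [n for n in self.graph.nodes if self.graph.degree(n) == 0]

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "r": d.get("weight", np.nan)}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"]).sort_values(
            ["gene_a", "gene_b"]
        ).reset_index(drop=True)


@dataclass
class TopologyStats:
    n_nodes: int
    n_edges: int
    average_degree: float
    clustering_coefficient: float
    average_path_length: float
    n_components: int

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "average_degree": self.average_degree,
            "clustering_coefficient": self.clustering_coefficient,
            "average_path_length": self.average_path_length,
            "n_components": self.n_components,
        }


def gene_correlations(awm) -> pd.DataFrame:
    """Pearson correlations between AWM gene rows across traits.

    Constant rows are excluded with a warning reporting how many were
    dropped.  Requires at least 3 trait columns.
    """
    z = awm.z if hasattr(awm, "z") else pd.DataFrame(awm)
    if z.shape[1] < 3:
        raise ValueError("need at least 3 trait columns for row correlations")
    sd = z.std(axis=1, ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        warnings.warn(
            f"excluding {len(const)} constant gene row(s) from correlations",
            stacklevel=2,
        )
        z = z.drop(index=const)
    r = np.corrcoef(z.to_numpy())
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=z.index, columns=z.index)


def build_network(
    mask, corr: pd.DataFrame, genes: list | None = None, census: list[str] | None = None
) -> CoAssocNetwork:
    """Assemble the network from a significance mask and correlations.

    ``mask`` must be symmetric and hollow.  Isolated genes are retained as
    nodes.  Regulator flags are set by case-insensitive symbol match against
    the census; an empty census leaves every flag False with a warning.
    """
    if isinstance(mask, pd.DataFrame):
        node_ids = list(mask.index)
        m = mask.to_numpy()
    else:
        m = np.asarray(mask, dtype=bool)
        node_ids = genes if genes is not None else list(range(m.shape[0]))
    if not np.array_equal(m, m.T):
        raise ValueError("significance mask must be symmetric")
    if np.any(np.diag(m)):
        raise ValueError("significance mask must be hollow (no self-edges)")

    census = census or []
    wanted = {s.strip().upper() for s in census if s.strip()}
    if not wanted:
        warnings.warn("empty regulator census: no regulator flags set", stacklevel=2)

    rmat = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    g = nx.Graph()
    for node in node_ids:
        g.add_node(node, is_regulator=str(node).upper() in wanted)
    ii, jj = np.nonzero(np.triu(m, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(node_ids[i], node_ids[j], weight=float(rmat[i, j]))
    return CoAssocNetwork(graph=g)


def topology_stats(
    network: CoAssocNetwork, clustering_mode: str = "zero_for_low_degree"
) -> TopologyStats:
    """Degree, clustering, path-length and component statistics.

    ``clustering_mode``: "zero_for_low_degree" (default; degree<2 nodes
    contribute 0 to the mean) or "exclude_low_degree".
    """
    g = network.graph
    nodes = list(g.nodes)
    n = len(nodes)
    adj = {v: set(g.neighbors(v)) for v in nodes}
    n_edges = sum(len(s) for s in adj.values()) // 2
    avg_degree = 2.0 * n_edges / n if n else 0.0

    # mean local clustering via neighbour-set intersections
    coeffs = []
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            if clustering_mode == "zero_for_low_degree":
                coeffs.append(0.0)
            continue
        links = 0
        nbrs = adj[v]
        for u in nbrs:
            links += len(adj[u] & nbrs)
        links //= 2
        coeffs.append(2.0 * links / (k * (k - 1)))
    clustering = float(np.mean(coeffs)) if coeffs else 0.0

    # BFS from every node: path lengths over connected distinct pairs
    total, pairs = 0, 0
    seen_components: set = set()
    n_components = 0
    for src in nodes:
        if src not in seen_components:
            n_components += 1
        dist = {src: 0}
        q = deque([src])
        while q:
            v = q.popleft()
            for u in adj[v]:
                if u not in dist:
                    dist[u] = dist[v] + 1
                    q.append(u)
        seen_components.update(dist)
        total += sum(dist.values())
        pairs += len(dist) - 1
    avg_path = total / pairs if pairs else 0.0

    return TopologyStats(
        n_nodes=n,
        n_edges=n_edges,
        average_degree=avg_degree,
        clustering_coefficient=clustering,
        average_path_length=avg_path,
        n_components=n_components,
    )


def write_graphml(path, network: CoAssocNetwork) -> None:
    """GraphML export (Cytoscape import format)."""
    nx.write_graphml(network.graph, path)
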