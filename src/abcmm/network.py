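"""Association networks, community detection and partition quality.

Nodes are conditions; an edge joins each pair whose association (ABC or RR)
is significant, weighted by the association value and signed by its side of
1. Communities come from Clauset-Newman-Moore greedy modularity
maximisation on the unweighted significant-edge graph, and partitions are
scored by modularity, coverage and performance.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_comm

__all__ = [
    "build_network",
    "detect_communities",
    "modularity",
    "coverage",
    "performance",
    "partition_report",
    "export_graph",
    "read_graphml",
]


def build_network(
    summaries: pd.DataFrame,
    labels: list[str],
    measure: str,
    value_column: str | None = None,
    prevalence: pd.Series | None = None,
) -> nx.Graph:
    """Graph of all conditions with one edge per significant pair.

    ``summaries`` needs columns i, j, significant and an association value
    column (``mode`` for ABC fits, ``rr`` for RR tables, or an explicit
    ``value_column``). Edge attributes: ``weight`` (the association value),
    ``sign`` ("positive"/"negative" by weight vs 1) and ``log_weight``
    (|log weight|, the display width scale). Node order follows the panel,
    which also fixes the community-detection tie-break order.
    """
    if value_column is None:
        value_column = {"ABC": "mode", "RR": "rr"}.get(measure, "value")
    g = nx.Graph(measure=measure)
    for k, lab in enumerate(labels):
        attrs = {"label": lab}
        if prevalence is not None:
            attrs["prevalence"] = float(prevalence.iloc[k])
        g.add_node(k, **attrs)
    for row in summaries.itertuples():
        if not getattr(row, "significant"):
            continue
        if bool(getattr(row, "degenerate", False)):
            continue
        w = float(getattr(row, value_column))
        if not w > 0:
            continue
        g.add_edge(
            int(row.i),
            int(row.j),
            weight=w,
            sign="positive" if w > 1 else "negative",
            log_weight=abs(float(np.log(w))),
        )
    return g


def detect_communities(
    net: nx.Graph, resolution: float = 1.0, positive_only: bool = False
) -> list[set]:
    """Clauset-Newman-Moore greedy modularity communities (unweighted).

    Returns a disjoint cover of all nodes. Edgeless graphs yield singleton
    clusters. ``positive_only`` restricts clustering to positive edges
    (negative-edge nodes stay in the graph). Deterministic for a fixed node
    insertion order.
    """
    g = net
    if positive_only:
        g = nx.Graph()
        g.add_nodes_from(net.nodes(data=True))
        g.add_edges_from(
            (u, v) for u, v, s in net.edges(data="sign") if s == "positive"
        )
    if g.number_of_edges() == 0:
        return [{n} for n in g.nodes]
    comms = nx_comm.greedy_modularity_communities(g, resolution=resolution, weight=None)
    partition = [set(c) for c in comms]
    covered = set().union(*partition)
    partition.extend({n} for n in g.nodes if n not in covered)
    return partition


def modularity(net: nx.Graph, partition: list[set], resolution: float = 1.0) -> float:
    """Newman modularity Q = sum_c [e_c/m - (d_c/2m)^2] on the unweighted
    significant-edge graph."""
    if net.number_of_edges() == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    return float(nx_comm.modularity(net, partition, weight=None, resolution=resolution))


def coverage(net: nx.Graph, partition: list[set]) -> float:
    """Fraction of edges that fall within clusters."""
    if net.number_of_edges() == 0:
        raise ValueError("coverage is undefined on an edgeless graph")
    return float(nx_comm.partition_quality(net, partition)[0])


def performance(net: nx.Graph, partition: list[set]) -> float:
    """Fraction of node pairs the partition classifies correctly:
    (within-cluster edges + between-cluster non-edges) / C(P, 2)."""
    p = net.number_of_nodes()
    if p < 2:
        raise ValueError("performance needs at least two nodes")
    if net.number_of_edges() == 0:
        # all correctly-classified pairs are between-cluster non-edges
        intra_pairs = sum(len(c) * (len(c) - 1) // 2 for c in partition)
        return 1.0 - intra_pairs / (p * (p - 1) / 2)
    return float(nx_comm.partition_quality(net, partition)[1])


def partition_report(net: nx.Graph, partition: list[set]) -> dict:
    """Partition plus its three quality scores, JSON-ready."""
    return {
        "measure": net.graph.get("measure"),
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "clusters": [sorted(c) for c in partition],
        "modularity": modularity(net, partition) if net.number_of_edges() else None,
        "coverage": coverage(net, partition) if net.number_of_edges() else None,
        "performance": performance(net, partition),
    }


def export_graph(
    net: nx.Graph,
    path: str | Path,
    partition: list[set] | None = None,
    fmt: str = "graphml",
) -> None:
    """Write the network as GraphML (lossless round-trip) or an edge-list
    CSV; cluster ids are attached as a node attribute when given."""
    g = net.copy()
    if partition is not None:
        for cid, cluster in enumerate(partition):
            for node in cluster:
                g.nodes[node]["cluster"] = cid
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "csv":
        rows = [
            {
                "i": u,
                "j": v,
                "condition_i": g.nodes[u].get("label", u),
                "condition_j": g.nodes[v].get("label", v),
                "weight": d["weight"],
                "sign": d["sign"],
            }
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["i", "j", "condition_i", "condition_j", "weight", "sign"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path, node_type=int)
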