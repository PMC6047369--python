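"""Weighted graph of the clustering, for assessment and visualization.

One node per cluster (stable set), weighted by its size; one edge per pair
of clusters joined by bridging paths, carrying the path count d_s and a
normalised adjacency score d in [0, 1] that measures how strongly the
bridging documents are tied to the two clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .covering import Covering
from .graph import ConflictGraph


@dataclass
class WeightedClusterGraph:
    """Quotient graph of a covering with size and bridge weights."""

    # cluster index -> sorted members
    clusters: dict[int, list[str]] = field(default_factory=dict)
    # (i, j) with i < j -> {"d_s": path count, "d": normalised score}
    edges: dict[tuple[int, int], dict] = field(default_factory=dict)

    def node_weight(self, i: int) -> int:
        return len(self.clusters[i])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, members in sorted(self.clusters.items()):
            g.add_node(i, size=len(members), members="|".join(members))
        for (i, j), w in sorted(self.edges.items()):
            g.add_edge(i, j, d_s=w["d_s"], d=w["d"])
        return g


def build_cluster_graph(c: Covering, g: ConflictGraph) -> WeightedClusterGraph:
    """Compute d_s (path count) and d (normalised inner-node adjacency).

    For clusters D_j, D_k bridged by paths P, with N(v) the neighbours of an
    inner node v in G over all edge colors:

        d_s = |P|
        d   = (1/|P|) * Σ_{(u,v,w) ∈ P} (|N(v) ∩ D_j| + |N(v) ∩ D_k|)
                                        / (|D_j| + |D_k|)
    """
    sets = c.stable_sets
    index = {s: i for i, s in enumerate(sets)}
    out = WeightedClusterGraph(
        clusters={i: sorted(s) for i, s in enumerate(sets)}
    )
    adj = g.adjacency()
    # collect paths per unordered cluster pair
    per_pair: dict[tuple[int, int], list] = {}
    for t in c.tuples:
        if not t.D2:
            continue
        i, j = index[t.D1], index[t.D2]
        a, b = min(i, j), max(i, j)
        per_pair.setdefault((a, b), []).extend(t.paths)
    for (a, b), paths in per_pair.items():
        dj = set(out.clusters[a])
        dk = set(out.clusters[b])
        denom = len(dj) + len(dk)
        score = 0.0
        for p in paths:
            nv = adj.get(p.inner, set())
            score += (len(nv & dj) + len(nv & dk)) / denom
        out.edges[(a, b)] = {"d_s": len(paths), "d": score / len(paths)}
    return out


def cluster_graph_to_dot(wg: WeightedClusterGraph) -> str:
    """DOT rendering: node size tracks cluster size, pen width tracks d."""
    lines = ["graph clustering {", "  node [shape=circle];"]
    for i, members in sorted(wg.clusters.items()):
        size = len(members)
        width = 0.5 + 0.15 * size
        lines.append(
            f'  {i} [label="{i}\\n({size})", width={width:.2f}, fixedsize=false];'
        )
    for (a, b), w in sorted(wg.edges.items()):
        pen = 1 + 4 * w["d"]
        lines.append(
            f'  {a} -- {b} [label="{w["d_s"]}", penwidth={pen:.2f},'
            f' weight={w["d"]:.4f}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_cluster_graph(wg: WeightedClusterGraph, path, fmt: str = "graphml") -> None:
    if fmt == "graphml":
        nx.write_graphml(wg.to_networkx(), path)
    elif fmt == "dot":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(cluster_graph_to_dot(wg))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_cluster_graph(path) -> WeightedClusterGraph:
    g = nx.read_graphml(path)
    wg = WeightedClusterGraph()
    for node, data in g.nodes(data=True):
        members = data.get("members", "")
        wg.clusters[int(node)] = members.split("|") if members else []
    for u, v, data in g.edges(data=True):
        a, b = sorted((int(u), int(v)))
        wg.edges[(a, b)] = {"d_s": int(data["d_s"]), "d": float(data["d"])}
    return wg
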