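"""Conflict graph construction, persistence and divide-and-conquer merging.

The conflict graph G = (V, E) connects *dissimilar* document pairs.  Given
two thresholds 0 < ι ≤ ε ≤ 1 on the normalised similarity scale, a pair
(x, y) receives

* no edge   if sim(x, y) > ε   (similar enough to share a cluster),
* a blue edge if ι ≤ sim(x, y) ≤ ε (borderline — may form a bridging path),
* a black edge if sim(x, y) < ι  (strongly dissimilar).

The blue subgraph B consists of the blue edges and their endpoints; setting
ι = ε makes B empty and recovers hard clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

Edge = frozenset  # unordered pair of node ids


def edge(u: str, v: str) -> Edge:
    if u == v:
        raise ValueError(f"self-loop on {u!r}")
    return frozenset((u, v))


@dataclass
class ConflictGraph:
    """Simple graph with black and blue edge classes and ε/ι metadata."""

    nodes: set[str] = field(default_factory=set)
    black_edges: set[Edge] = field(default_factory=set)
    blue_edges: set[Edge] = field(default_factory=set)
    eps: float | None = None
    iota: float | None = None
    measure: str = ""

    def __post_init__(self) -> None:
        overlap = self.black_edges & self.blue_edges
        if overlap:
            raise ValueError(f"edges both black and blue: {sorted(map(sorted, overlap))}")
        for e in self.black_edges | self.blue_edges:
            if len(e) != 2:
                raise ValueError(f"malformed edge {set(e)}")
            if not e <= self.nodes:
                raise ValueError(f"edge {sorted(e)} has endpoint outside node set")

    # -- basic queries ------------------------------------------------------

    @property
    def edges(self) -> set[Edge]:
        return self.black_edges | self.blue_edges

    def blue_nodes(self) -> set[str]:
        """Endpoints of blue edges (the node set of B, derived)."""
        out: set[str] = set()
        for e in self.blue_edges:
            out |= e
        return out

    def has_edge(self, u: str, v: str) -> bool:
        return edge(u, v) in self.black_edges or edge(u, v) in self.blue_edges

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for e in self.edges:
            u, v = tuple(e)
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def blue_adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for e in self.blue_edges:
            u, v = tuple(e)
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def neighbors(self, v: str) -> set[str]:
        return {next(iter(e - {v})) for e in self.edges if v in e}

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConflictGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.black_edges == other.black_edges
            and self.blue_edges == other.blue_edges
        )

    # -- conversion ---------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        if self.eps is not None:
            g.graph["eps"] = self.eps
        if self.iota is not None:
            g.graph["iota"] = self.iota
        g.graph["measure"] = self.measure
        g.add_nodes_from(sorted(self.nodes))
        for e in sorted(self.black_edges, key=sorted):
            u, v = sorted(e)
            g.add_edge(u, v, blue=False)
        for e in sorted(self.blue_edges, key=sorted):
            u, v = sorted(e)
            g.add_edge(u, v, blue=True)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "ConflictGraph":
        black, blue = set(), set()
        for u, v, data in g.edges(data=True):
            if "blue" not in data:
                raise ValueError(f"edge ({u}, {v}) lacks the 'blue' attribute")
            b = data["blue"]
            if isinstance(b, str):
                b = b.strip().lower() in ("true", "1", "yes")
            (blue if b else black).add(edge(str(u), str(v)))
        return cls(
            nodes={str(v) for v in g.nodes},
            black_edges=black,
            blue_edges=blue,
            eps=g.graph.get("eps"),
            iota=g.graph.get("iota"),
            measure=str(g.graph.get("measure", "")),
        )


@dataclass(frozen=True, order=True)
class BlueTriple:
    """A 3-node path (i, v, j) with both edges blue; i < j canonically."""

    i: str
    v: str
    j: str

    def __post_init__(self) -> None:
        if len({self.i, self.v, self.j}) != 3:
            raise ValueError("triple nodes must be distinct")
        if self.i > self.j:
            raise ValueError("triple endpoints must satisfy i < j")


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def classify_pair(sim_value: float, eps: float, iota: float) -> str:
    """'none', 'blue' or 'black' for one pair under the threshold rule."""
    if sim_value > eps:
        return "none"
    if sim_value >= iota:
        return "blue"
    return "black"


def build_graph(sim: SimilarityMatrix, eps: float, iota: float) -> ConflictGraph:
    """Threshold a similarity matrix into a conflict graph."""
    if not (0 < iota <= eps <= 1):
        raise ValueError(f"need 0 < iota <= eps <= 1, got iota={iota}, eps={eps}")
    if not sim.normalized:
        logger.warning("similarity matrix not normalised; normalising first")
        sim = sim.normalize()
    g = ConflictGraph(
        nodes=set(sim.ids), eps=eps, iota=iota, measure=sim.measure
    )
    ids = sim.ids
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            kind = classify_pair(float(sim.values[a, b]), eps, iota)
            if kind == "blue":
                g.blue_edges.add(edge(ids[a], ids[b]))
            elif kind == "black":
                g.black_edges.add(edge(ids[a], ids[b]))
    return g


def enumerate_blue_triples(g: ConflictGraph) -> list[BlueTriple]:
    """All 3-node blue paths (i, v, j), each unordered endpoint pair once."""
    adj = g.blue_adjacency()
    triples = []
    for v in sorted(g.nodes):
        nbrs = sorted(adj[v])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                triples.append(BlueTriple(nbrs[a], v, nbrs[b]))
    return sorted(triples)


# ---------------------------------------------------------------------------
# Divide and conquer
# ---------------------------------------------------------------------------


def merge_graphs(
    g1: ConflictGraph, g2: ConflictGraph, sim_provider
) -> ConflictGraph:
    """Union two disjoint partial graphs and classify all cross pairs.

    ``sim_provider(x, y)`` must return the similarity of any cross pair on the
    union corpus (a SimilarityMatrix works).  The result equals the graph the
    monolithic build would produce on the union.
    """
    if g1.nodes & g2.nodes:
        raise ValueError(f"node sets overlap: {sorted(g1.nodes & g2.nodes)}")
    for attr in ("eps", "iota", "measure"):
        if getattr(g1, attr) != getattr(g2, attr):
            raise ValueError(
                f"metadata mismatch on {attr}: {getattr(g1, attr)!r} vs "
                f"{getattr(g2, attr)!r}"
            )
    if g1.eps is None or g1.iota is None:
        raise ValueError("graphs must carry eps/iota metadata to be merged")
    get = sim_provider.get if isinstance(sim_provider, SimilarityMatrix) else sim_provider
    merged = ConflictGraph(
        nodes=g1.nodes | g2.nodes,
        black_edges=set(g1.black_edges | g2.black_edges),
        blue_edges=set(g1.blue_edges | g2.blue_edges),
        eps=g1.eps,
        iota=g1.iota,
        measure=g1.measure,
    )
    for u in sorted(g1.nodes):
        for v in sorted(g2.nodes):
            kind = classify_pair(float(get(u, v)), merged.eps, merged.iota)
            if kind == "blue":
                merged.blue_edges.add(edge(u, v))
            elif kind == "black":
                merged.black_edges.add(edge(u, v))
    return merged


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_graph(g: ConflictGraph, path) -> None:
    """Write GraphML with a boolean 'blue' edge attribute and ε/ι metadata."""
    nx.write_graphml(g.to_networkx(), path)


def load_graph(path) -> ConflictGraph:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # malformed XML / missing file
        raise ValueError(f"cannot parse GraphML at {path}: {exc}") from exc
    return ConflictGraph.from_networkx(g)


def to_dot(g: ConflictGraph) -> str:
    """DOT rendering; blue edges drawn blue, black edges black."""
    lines = ["graph conflict {"]
    for v in sorted(g.nodes):
        lines.append(f'  "{v}";')
    for e in sorted(g.black_edges, key=sorted):
        u, v = sorted(e)
        lines.append(f'  "{u}" -- "{v}" [color=black];')
    for e in sorted(g.blue_edges, key=sorted):
        u, v = sorted(e)
        lines.append(f'  "{u}" -- "{v}" [color=blue];')
    lines.append("}")
    return "\n".join(lines) + "\n"
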