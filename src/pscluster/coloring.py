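"""Starting proper colorings of the conflict graph.

Three heuristics supply the initial partition into stable sets that the
greedy eliminator works on: greedy independent sets (GIS), saturation
largest first (SLF / DSATUR), and a clique partition of the complement
graph (Tseng-style pairwise merging).  All tie-breaks fall back to the
lexicographic node id, so every heuristic is deterministic; an optional
seed permutes the tie-break priority instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import ConflictGraph


@dataclass
class Coloring:
    """Proper coloring: node id -> color in 1..k, adjacent nodes differ."""

    assignment: dict[str, int] = field(default_factory=dict)

    @property
    def num_colors(self) -> int:
        return max(self.assignment.values(), default=0)

    def classes(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for v, c in self.assignment.items():
            out.setdefault(c, set()).add(v)
        return out

    def renumbered(self) -> "Coloring":
        """Contiguous colors 1..k in order of each class's smallest node id."""
        classes = self.classes()
        order = sorted(classes, key=lambda c: min(classes[c]))
        remap = {old: new for new, old in enumerate(order, start=1)}
        return Coloring({v: remap[c] for v, c in self.assignment.items()})


def _priority(nodes, seed) -> dict[str, int]:
    """Tie-break rank per node: lexicographic, or a seeded permutation."""
    ordered = sorted(nodes)
    if seed is not None:
        rng = np.random.default_rng(seed)
        ordered = [ordered[i] for i in rng.permutation(len(ordered))]
    return {v: i for i, v in enumerate(ordered)}


def gis_coloring(g: ConflictGraph, seed: int | None = None) -> Coloring:
    """Greedy independent sets: peel off maximal stable sets, one per color.

    Within the residual graph, nodes are taken min-degree-first; each chosen
    node and its neighbours are excluded from the current set.
    """
    prio = _priority(g.nodes, seed)
    adj = g.adjacency()
    remaining = set(g.nodes)
    assignment: dict[str, int] = {}
    color = 0
    while remaining:
        color += 1
        candidates = set(remaining)
        while candidates:
            u = min(candidates, key=lambda v: (len(adj[v] & candidates), prio[v]))
            assignment[u] = color
            candidates -= adj[u]
            candidates.discard(u)
        remaining -= {v for v, c in assignment.items() if c == color}
    return Coloring(assignment).renumbered()


def slf_coloring(g: ConflictGraph, seed: int | None = None) -> Coloring:
    """Saturation-largest-first (DSATUR).

    Repeatedly color the uncolored node with the most distinct neighbour
    colors; ties broken by degree (descending) then node priority; the
    smallest feasible color is assigned.
    """
    prio = _priority(g.nodes, seed)
    adj = g.adjacency()
    neighbor_colors: dict[str, set[int]] = {v: set() for v in g.nodes}
    assignment: dict[str, int] = {}
    uncolored = set(g.nodes)
    while uncolored:
        u = min(
            uncolored,
            key=lambda v: (-len(neighbor_colors[v]), -len(adj[v]), prio[v]),
        )
        used = neighbor_colors[u]
        c = 1
        while c in used:
            c += 1
        assignment[u] = c
        uncolored.discard(u)
        for w in adj[u]:
            neighbor_colors[w].add(c)
    return Coloring(assignment).renumbered()


def tseng_clique_partition(g: ConflictGraph, seed: int | None = None) -> Coloring:
    """Clique partition of the complement graph by iterative pair merging.

    Super-nodes start as singletons.  While some pair of super-nodes is
    adjacent in the complement (mergeable into one clique), the pair with
    the most common complement-neighbours is merged.  Each final super-node
    is a clique of the complement, i.e. a stable set of G — one color class.
    """
    prio = _priority(g.nodes, seed)
    nodes = sorted(g.nodes, key=lambda v: prio[v])
    adj = g.adjacency()
    # complement adjacency between super-nodes: mergeable iff no G-edge
    # between any pair of their members
    groups: dict[str, set[str]] = {v: {v} for v in nodes}
    comp: dict[str, set[str]] = {
        v: {w for w in nodes if w != v and w not in adj[v]} for v in nodes
    }
    while True:
        best = None
        for u in sorted(groups, key=lambda v: prio[v]):
            for w in sorted(comp[u] & set(groups), key=lambda v: prio[v]):
                if prio[w] <= prio[u]:
                    continue
                common = len(comp[u] & comp[w])
                if best is None or common > best[0]:
                    best = (common, u, w)
        if best is None:
            break
        _, u, w = best
        groups[u] |= groups[w]
        comp[u] &= comp[w]
        del groups[w]
        for v in comp:
            v_comp = comp[v]
            v_comp.discard(w)
            if u in v_comp and v not in comp[u]:
                v_comp.discard(u)
    assignment: dict[str, int] = {}
    for color, rep in enumerate(sorted(groups, key=lambda v: prio[v]), start=1):
        for v in groups[rep]:
            assignment[v] = color
    return Coloring(assignment).renumbered()


def validate_coloring(g: ConflictGraph, c: Coloring) -> tuple[bool, list[str]]:
    """Check that every node is colored and no edge is monochromatic."""
    violations = []
    for v in sorted(g.nodes):
        if v not in c.assignment:
            violations.append(f"node {v} uncolored")
    for e in sorted(g.edges, key=sorted):
        u, v = sorted(e)
        if c.assignment.get(u) is not None and c.assignment.get(u) == c.assignment.get(v):
            violations.append(f"edge ({u}, {v}) monochromatic (color {c.assignment[u]})")
    return (not violations, violations)


HEURISTICS = {
    "gis": gis_coloring,
    "slf": slf_coloring,
    "clique": tseng_clique_partition,
}
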